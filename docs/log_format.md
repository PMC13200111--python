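# The PQA1 delivery-log format

Vendor delivery logs ("demand data") for synchrotron pencil-beam-scanning
systems are proprietary binary files. `protonqa` neither decodes nor emulates
any vendor layout; it defines its own openly documented, versioned format
carrying the same content, so that every pipeline stage is testable without
clinical data.

All integers and floats are **little-endian**. One file holds one delivery
session (one plan delivery in one treatment room on one date).

## Header

| offset | size | type   | field                                   |
|-------:|-----:|--------|-----------------------------------------|
| 0      | 4    | bytes  | magic `PQA1`                            |
| 4      | 2    | uint16 | format version (currently `1`)          |
| 6      | 2    | uint16 | room-tag byte length `L_r`              |
| 8      | L_r  | utf-8  | room tag (e.g. `G1`)                    |
| ..     | 10   | ascii  | ISO-8601 calendar date `YYYY-MM-DD`     |
| ..     | 2    | uint16 | plan-id byte length `L_p`               |
| ..     | L_p  | utf-8  | plan id                                 |
| ..     | 4    | uint32 | energy-layer count `N_L`                |

## Layer blocks (repeated `N_L` times, in delivery order)

| size | type    | field                          |
|-----:|---------|--------------------------------|
| 8    | float64 | nominal beam energy (MeV)      |
| 4    | uint32  | spot count `n`                 |
| 56·n | records | `n` spot records (below)       |

## Spot record (56 bytes, seven float64 values in this order)

1. `layer_index` — 0-based energy-layer index
2. `spot_index` — 0-based delivery order within the layer
3. `x_spm` — spot x position in the SPM plane (mm)
4. `y_spm` — spot y position in the SPM plane (mm)
5. `width_x` — spot width in x (mm)
6. `width_y` — spot width in y (mm)
7. `mu_delivered` — delivered monitor units for this spot (MU, non-cumulative)

## Guarantees

- `write_log` → `read_log` is the identity on every field.
- Two writes of the same session are byte-identical.
- The file size is exactly `header + N_L·12 + 56·(total spots)` bytes and is
  computable from the header alone (`protonqa.log_io.expected_file_size`).
- Bad magic or an unknown version raises a format error; any truncation
  raises a corruption error reporting the byte offset, and no partial
  session is ever returned.

Positions are stored in the **SPM plane**; multiply by the projection
factors (defaults `f_x = 1.696`, `f_y = 1.391`) to obtain isocenter-plane
coordinates. Spot widths are carried for format fidelity but are not used by
any QA statistic. Logged dose is per-spot MU, not cumulative.
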