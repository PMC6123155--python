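# Trace file dialects

Both dialects are plain text, newline-terminated, and share the convention
that the two files of a simultaneously recorded pair use the same time origin
t = 0 (the shared start trigger). Beam intervals are half-open `[on, off)`
everywhere in the package.

## `rpm_vxp_like` (displacement-style, extension `.vxp` by convention)

Header: three `#`-prefixed `key=value` lines, in this order:

```
#version=1
#samples_per_second=25.0
#scale_factor=1.0
```

Then one comma-separated line per sample with seven fields:

```
amplitude,phase_placeholder,timestamp_ms,valid_flag,ttl_in,mark,ttl_out
```

| field | meaning |
|---|---|
| `amplitude` | float, full `repr` precision, may be negative |
| `phase_placeholder` | always `0` (reserved) |
| `timestamp_ms` | integer milliseconds — round-trip quantization is at most 1 ms |
| `valid_flag` | always `1` |
| `ttl_in` | `1` on the sample where the beam turns ON, else `0` |
| `mark` | empty, `P` (EOI, end-of-inhalation peak) or `Z` (EOE, end-of-exhalation valley) |
| `ttl_out` | `1` on the first sample where the beam is OFF again, else `0` |

`ttl_in`/`ttl_out` are edge indicators: the sample carrying `ttl_in=1` is
beam-on; the sample carrying `ttl_out=1` is beam-off (half-open interval). A
`ttl_in` without a matching `ttl_out` before EOF leaves the beam on through
the final sample (a warning is logged).

Byte-level example (three samples at 25 Hz, one beam segment starting at the
second sample and still open at EOF, EOI marked on the second sample):

```
#version=1
#samples_per_second=25.0
#scale_factor=1.0
0.0,0,0,1,0,,0
50.0,0,40,1,1,P,0
100.0,0,80,1,0,,0
```

## `anzai_csv_like` (pressure-style, extension `.csv` by convention)

Header line `time_s,pressure,ttl`, then one row per sample. `time_s` and
`pressure` are full-precision floats; `ttl` is the per-sample beam level
(`1` = beam on). Example:

```
time_s,pressure,ttl
0.0,12.5,0
0.025,13.1,1
0.05,13.9,1
```

## Ground-truth TSV

`simulate` also writes the internal motion as a tab-separated file with
header `time_s  internal_amplitude  amplitude_fraction`, where
`amplitude_fraction` is the amplitude normalized to [0, 1] over the trace
(0 = end of exhalation), ready to drive the digital phantom.

## Conversion

`respsurro convert --anzai IN.csv --rpm-ref REF.vxp --out OUT.vxp` re-badges
the pressure trace in the displacement dialect, keeping its timestamps and
amplitudes bit-exactly and transferring beam state from the reference by
timestamp alignment: a pressure sample is beam-on iff its timestamp lies in a
reference on-segment (closed left, open right). No resampling or time
realignment is performed.

These dialects are local to this package: they carry the *content* the
analysis needs (amplitudes, timestamps, TTL in/out events, extrema marks) and
make no claim about proprietary vendor layouts.
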