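# respsurro

Discrepancy analysis between paired respiratory surrogate signals, and its
propagation through 4D-CT local-amplitude phase sorting and respiratory
gating.

Two external surrogates recorded on the same patient (an infrared-marker
anterior–posterior displacement signal and an abdominal-belt pressure signal)
generally disagree: the pressure signal tends to reach end-of-inhalation a
fraction of a second earlier (a phase shift) and to fall more steeply during
exhalation (a shape distortion). `respsurro` provides a tested, reusable
pipeline that

- **simulates** paired surrogate traces from a quasi-periodic breathing model
  with known injected lag, per-limb time warps, nonlinearity and noise
  (`synthetic_respiration`), so every stage is testable without patient data;
- **reads/writes** two plain-text trace dialects (a displacement-style
  VXP-like file and a pressure CSV) and converts between them with beam
  (TTL) markers transferred (`io_formats`, see `docs/formats.md`);
- **analyzes** traces: global 0–100 renormalization, windowed extrema search
  with a programmatic manual-override hook, cycle segmentation, paired
  period/depth statistics, whole-trace correlation (`trace_analysis`);
- **estimates the phase shift** per cycle from EOI latencies and, as an
  alternative route, from a direct least-squares ellipse fit to the
  correlation scatter (`phase_shift`);
- **compares cycle shapes**: per-cycle renormalized, EOI-aligned average
  curves and a calibrated limb-steepness classifier (`cycle_shape`);
- **sorts samples into 10 respiratory phases** by local amplitude fraction
  (phases 1–10 = 100%Ex … 80%In) (`phase_sorting`);
- **propagates the discrepancy into anatomy** with a digital motion phantom:
  the same cine acquisition sorted by each surrogate yields per-phase lung
  volumes and diaphragm apex positions (2 mm slice quantization) and their
  single-phase differences (`phantom_4d`);
- **quantifies gating mismatch**: a gating window defined on one surrogate
  applied during delivery monitored by the other — duty cycles, beam-on
  overlap, residual motion (`gating_analysis`).

## Command line

All commands write machine-readable JSON and exit nonzero on error.

```bash
# synthetic pair: displacement .vxp, pressure .csv, ground-truth .tsv
respsurro simulate --config examples/study.yml --out-dir sim/

# pressure -> displacement dialect with TTL markers transferred
respsurro convert --anzai sim/surrogate_b.csv --rpm-ref sim/surrogate_a.vxp --out sim/b_conv.vxp

# cycle statistics + correlation; phase shift (both estimators); shapes
respsurro analyze --a sim/surrogate_a.vxp --b sim/surrogate_b.csv --report analysis.json
respsurro shift   --a sim/surrogate_b.csv --a-dialect anzai --b sim/surrogate_a.vxp --b-dialect rpm --method both --report shift.json
respsurro shape   --a sim/surrogate_a.vxp --b sim/surrogate_b.csv --report shape.json --plot shape.png

# 10-phase local-amplitude sorting; phantom comparison; gating mismatch
respsurro sort    --trace sim/surrogate_a.vxp --out sorted.csv
respsurro phantom --internal sim/ground_truth.tsv --surrogate-a sim/surrogate_a.vxp --surrogate-b sim/surrogate_b.csv --report phantom.json
respsurro gate    --window gate.yml --design sim/surrogate_a.vxp --applied sim/surrogate_b.csv --internal sim/ground_truth.tsv --report gate.json

# one-command synthetic-cohort study (simulate + all analyses + report.json)
respsurro report --seed 1 --out-dir study/
```

Sign convention throughout: a **positive** phase shift means the first trace
passed to the estimator reaches end-of-inhalation **earlier**.

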