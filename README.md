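# cupversion

Radiographic measurement of acetabular-component anteversion after
total hip arthroplasty, rebuilt as a fully synthetic, testable
pipeline.

Six published plain-film measurement methods (five AP ellipse-based
formulas and the direct cross-table lateral reading) are compared for
reliability and accuracy against an edge-detection reference pipeline
(circle fits to the prosthetic head and cup shell, then a constrained
opening-ellipse reconstruction).  Because the original study's
radiographs are not available, the package replaces them with a
projection simulator whose ground truth is known: a hemispherical cup
plus head sphere is projected analytically (parallel or point-source
beam) and by an independent brute-force ray tracer, landmarks are
extracted per method, and an observer-noise model emulates three
observers reading twice.

## Layout

| module | contents |
|---|---|
| `cupversion.geometry` | cup pose / beam / ellipse types, AP and cross-table lateral projection, ray-traced silhouette oracle |
| `cupversion.landmarks` | per-method landmark extraction and the observer jitter/bias model |
| `cupversion.methods` | the six anteversion formulas |
| `cupversion.reference` | edge-detection reference: circle fits, constrained ellipse reconstruction, image route via marching squares |
| `cupversion.cohort` | synthetic study cohort (71 patients, 3 observers × 2 sessions by default) |
| `cupversion.stats` | ICC(2,1) with F-based 95% CI, paired accuracy, study-shaped tables |
| `cupversion.cli` / `cupversion.io` | `cupver` command line and CSV/JSON round-tripping |

## CLI

```sh
cupver simulate --config cfg.yaml --seed 1 --out cohort_out/
#   -> cohort_truth.csv, records.csv, provenance.yaml
cupver measure landmarks.csv --methods lewinnek,widmer --out records.csv
cupver analyze cohort_out/records.csv --out tables/
#   -> table2_reliability.csv, table3_accuracy.csv, tables.md
cupver render --seed 1 --out png/        # ray-traced silhouette PNGs
```

The config is YAML with the fields of `CohortConfig` (all optional);
unknown keys are rejected.  All randomness flows from the single seed
and reruns are byte-identical.

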