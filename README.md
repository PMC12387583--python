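# vergesim

Headless, seedable simulator and scoring pipeline for a VR-style distance
horizontal fusional-vergence screening task.

A virtual balloon (50 cm diameter) sits 6 m ahead of the observer, randomly
shifted 0/50/100 cm laterally. A vergence demand is imposed by rotating one
eye's virtual camera by 0, 10 or 20 prism diopters (PD), inward (demanding
divergence, NFV) or outward (demanding convergence, PFV). The observer
shoots at the perceived balloon centre; the horizontal angular error between
hit point and balloon centre is the *hitting deviation* (θ_HD), and the
achieved *horizontal fusional vergence* is

```
HFV = θ_CR − θ_HD
```

where θ_CR is the imposed camera-rotation demand. `vergesim` replaces the
headset and the human with a parametric synthetic observer so the protocol,
its scoring and its statistics can be exercised end to end without hardware.

## What's inside

| module | role |
| --- | --- |
| `vergesim.geometry` | PD ↔ degree ↔ world-coordinate conversions, hitting-deviation computation |
| `vergesim.subject_model` | clamp-model synthetic observer, folded-normal aiming error, cohort sampling |
| `vergesim.protocol` | five-condition session engine, per-shot randomization, shot-record CSV I/O |
| `vergesim.scoring` | per-condition θ_HD, HFV/total vergence, two-stage cohort summaries |
| `vergesim.stats` | Shapiro–Wilk-gated paired t / Wilcoxon comparisons vs control, SSQ scoring |
| `vergesim.config` / `vergesim.cli` | YAML configuration and the command-line surface |

The observer model is a hard clamp: a demand at or below the subject's
fusional amplitude is met in full (hit lands on the balloon centre, up to a
baseline aiming error of 0.65 ± 0.25 PD); demand beyond the amplitude leaves
the full residual as hitting deviation.

## CLI

```bash
# simulate a synthetic cohort through the full protocol
vergesim simulate --seed 1 --out shots.csv            # default 19 subjects
vergesim simulate --config my.yaml --seed 1 --out shots.csv

# score shot records (also accepts externally logged data in the same CSV layout)
vergesim score shots.csv --out report.json --table table.csv

# paired condition-vs-control comparisons
vergesim compare shots.csv --out comparisons.json

# Simulator Sickness Questionnaire (columns: subject_id,phase,item,score)
vergesim ssq ssq.csv --out ssq_report.json

# end-to-end seeded demo run
vergesim demo --seed 1 --out demo_out
```

Config YAML has four optional sections — `world:`, `cohort:`, `protocol:`,
`stats:` — mirroring the dataclasses in `vergesim.config`; the resolved
configuration is echoed into every report for provenance.

Shot-record CSV columns:
`subject_id,condition,shot_index,control_eye,balloon_x_m,balloon_y_m,balloon_z_m,hit_x_m,hit_y_m,hit_z_m,deviation_pd`.

## Notes

- All prism-diopter conversions use the exact deflection definition
  (`pd = 100·tan θ`), never a small-angle approximation.
- Scoring uses the mean **absolute** deviation per condition; signed
  per-shot deviations are preserved in the records for diagnostics.
- Randomness is hierarchical: a master seed spawns one substream per
  subject keyed on the subject id, so cohort edits never perturb other
  subjects' records and reruns are byte-identical.
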