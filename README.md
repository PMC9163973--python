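# tunnelgeom

3D simulation of tibial-tunnel geometry for transtibial posterior cruciate
ligament (PCL) reconstruction.

In transtibial PCL reconstruction a bone tunnel is drilled through the
proximal tibia to the tibial PCL attachment. Steeper tunnels reduce the
"killer turn" — the sharp graft bend at the posterior aperture — but an
over-inclined tunnel breaks the posterior tibial cortex. For each of the
five classical entry approaches (T1 anterior-1/3 and T2 midpoint of the
anteromedial cortex flat, T3 tibial crest, T4 anterior-1/3 and T5 midpoint
of the anterolateral flat), `tunnelgeom` solves for the **permissive safe
angle**

> PSA = max { ∠(tunnel centerline, plane M) : the 5-mm-radius cylinder with
> its exit fixed at the PCL attachment leaves the posterior cortex intact }

where plane M is the medial tibial plateau plane through the rim landmarks
E (anterior peak), F (most medial point) and G (posterior peak) found via a
best-fit circle on the medial plateau rim. It also reports the tunnel height
TTH (entry point to plane M) and depth TTD (entry-to-exit length), and runs
the cohort statistics layer (approach-wise ANOVA with compact letters, sex
t-tests, age/height subgroup ANOVAs, inter-observer ICC, noncentral-F
sample-size computation).

The package is aimed at surgical-planning and computational-anatomy work:
it ships a parametric proximal-tibia generator (watertight meshes with
analytic ground-truth landmarks), so the whole pipeline is testable without
clinical CT data, and it accepts user-supplied STL/PLY meshes with a JSON
landmark sidecar.

## Worked example

```python
import dataclasses
from tunnelgeom import RunConfig, run_cohort
from tunnelgeom.stats import run_subgroup_analysis

cfg = dataclasses.replace(RunConfig(), n_subjects=30, seed=0)
df = run_cohort(cfg, write=False)
print(df.groupby("approach")[["psa_deg", "tth_mm", "ttd_mm"]].mean().round(2))
```

prints

```
          psa_deg  tth_mm  ttd_mm
approach
T1          61.48   55.08   57.45
T2          60.98   43.97   45.01
T3          58.58   80.00   88.34
T4          50.29   51.11   60.37
T5          45.75   41.60   51.60
```

Each row is the cohort mean over 30 synthetic subjects: the anteromedial
approaches permit the steepest safe tunnels (~61°), the crest is
intermediate, and the anterolateral approaches are the shallowest (~46–50°)
— the entry azimuth relative to the exit's sagittal plane is what lowers
the safe angle. TTH/TTD are the matching drill-guide height and reamer
depth in millimetres.

The same pipeline is scriptable from the shell:

```bash
tunnelgeom generate --n 5 --seed 1 --out-dir meshes/      # meshes + sidecars
tunnelgeom cohort --n 30 --seed 0 --out-dir results/      # measurements.csv
tunnelgeom stats results/measurements.csv --out-dir results/
tunnelgeom measure meshes/S000.stl meshes/S000.landmarks.json
```

`stats` writes the per-approach summary with compact significance letters
(`fig5_summary.csv`) and the sex/age/height subgroup tables
(`table1_sex.csv`, `table2_age.csv`, `table3_height.csv`).

## Layout

- `src/tunnelgeom/synthetic.py` — parametric tibia generator and cohort sampler
- `src/tunnelgeom/cross_section.py` — axial outlines, cortex flats, T1–T5 entry tracks
- `src/tunnelgeom/plateau.py` — medial rim extraction and plane M
- `src/tunnelgeom/solver.py` — posterior-cortex clearance and the max-angle solve
- `src/tunnelgeom/measure.py` — PSA/TTH/TTD and the plane-N angle witness
- `src/tunnelgeom/stats.py` — ANOVA, t-test, ICC, compact letters, power/sample size
- `src/tunnelgeom/pipeline.py`, `cli.py` — cohort runs, mesh/sidecar I/O, CLI

See `docs/methods.md` for the model, its assumptions, parameter defaults
and known limitations.
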