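# virtuheart

Personalized virtual-heart modeling of ventricular-arrhythmia (VA) risk in
hypertrophic cardiomyopathy (HCM).

HCM hearts harbor two kinds of fibrotic remodeling: dense (focal) fibrosis —
replacement scar, electrically inexcitable — and diffuse interstitial
fibrosis, which conducts but with remodeled myocyte electrophysiology.
Standard LGE-CMR thresholding (>3 SD and >5 SD above the remote-myocardium
mean) detects scar well but badly underestimates diffuse fibrosis.
`virtuheart` implements the fused LGE+T1 pipeline: a single postcontrast T1
map (dense < 350 ms, diffuse 350–450 ms relaxation times) re-derives
*personalized* LGE thresholds (T_Diffuse, T_Dense, in SD units) by quantile
matching on the matching slice, which are then applied to the whole stack.
The resulting substrate model is probed electrophysiologically: an
anisotropic monodomain reaction–diffusion model with a human ventricular
myocyte model (ten Tusscher 2006 formulation plus late sodium current) in
two variants,

* **normal** — calibrated so steady 1 Hz pacing gives APD90 = 280 ms;
* **remodeled** (diffuse fibrosis) — I_NaL ×2.07, I_CaL ×1.19, I_Kr ×0.66,
  I_Ks ×0.73, I_to ×0.15, I_K1 ×0.85, Na/Ca exchanger ×1.34, SERCA ×0.57,
  which prolongs APD90 to ≈330 ms (+18%) and flattens the phase-1 notch —

and rapid pacing (S1 drive + decremental extrastimuli) from seven
endocardial AHA-style sites.  A heart is *at risk* when reentry is induced
from at least one site; predictions are scored against clinical outcomes
with standard confusion metrics.

Everything runs on synthetic data: the package generates annular-LV LGE/T1
image pairs with controlled fibrosis burdens, annular 2-D substrate phantoms
(protected-isthmus scar, diffuse patches), and the 26-patient cohort-outcome
fixture used for the predictive-performance table.

## Worked example

```python
from virtuheart import fusion, synthetic

spec = synthetic.SyntheticCohortSpec(seed=1)   # cohort-mean burdens
stack, t1, truth = synthetic.generate_lge_t1_pair(spec)

thr, labels, fr = fusion.fuse(stack, t1, mode="lge_t1")
_, _, fr0 = fusion.fuse(stack, t1, mode="lge_only")
print(f"T_Diffuse = {thr.t_diffuse:.2f} SD, T_Dense = {thr.t_dense:.2f} SD")
print(f"diffuse fibrosis: {fr.diffuse_pct:.1f}% (LGE-T1) "
      f"vs {fr0.diffuse_pct:.1f}% (LGE only)")
```

prints

```
T_Diffuse = 0.75 SD, T_Dense = 6.16 SD
diffuse fibrosis: 41.7% (LGE-T1) vs 10.3% (LGE only)
```

— the T1 information collapses the diffuse threshold from the
one-size-fits-all 3 SD to ≈1 SD, revealing roughly four times more diffuse
fibrosis; the dense threshold stays near 5 SD.  Single-cell
electrophysiology:

```python
from virtuheart import ionic
print(ionic.apd90(ionic.make_params("normal")))     # 280.0 ms
print(ionic.apd90(ionic.make_params("remodeled")))  # 333.1 ms  (+19%)
```

The predictive-performance table of the cohort fixture:

```python
from virtuheart import risk, synthetic
print(risk.reproduce_table3(synthetic.cohort_outcomes_fixture()))
```

```
                                    sensitivity  specificity   ppv   npv  accuracy
ACCF/AHA risk model                        46.2         46.2  46.2  46.2      46.2
ESC risk model                             53.9         38.5  46.7  45.5      46.2
Virtual-heart technology: LGE-T1           84.6         76.9  78.6  83.3      80.8
Virtual-heart technology: LGE only         69.2         76.9  75.0  71.4      73.1
```

The fused LGE-T1 virtual heart identifies 11 of 13 patients with clinical VA
(sensitivity 84.6%) versus 6–7 for the clinical risk scores.

A CLI mirrors the library: `virtuheart fuse`, `virtuheart cell`,
`virtuheart induce`, `virtuheart run` (see `--help`).

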