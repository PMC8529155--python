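# fidmargin

Margin determination for fiducial-tracking lung stereotactic ablative
radiotherapy (SABR).

When lung metastases are treated with a robotic tracking system, the beam
follows implanted gold fiducial markers rather than the tumor itself.  If
the markers are few, or far from the target — as with intraoperatively
implanted markers — the tumor and the tracked markers do not breathe in
perfect unison, and the residual target-to-marker motion discrepancy must
be covered by an extra internal-target-volume margin (the *ITV_tracking*
margin).  `fidmargin` implements the full desk pipeline for quantifying
that margin:

1. **Synthetic respiratory phantom** — deterministic ten-phase 4D CT of a
   lung-density background with small gold-seed capsules (and an optional
   spherical GTV insert) moving under the cos⁴ breathing model
   z(t) = z₀ − b·cos⁴(πt/τ).
2. **Marker detection** — HU thresholding (HU > 1500), 26-connected
   components, intensity-weighted sub-voxel centroids.
3. **Template tracking** — per marker, the translation from the 0% phase
   to each other phase that maximizes mutual information between a
   4 × 4 × 10 mm template and the target phase, searched multi-resolution
   from a 1.0 mm grid down to 0.25 mm.
4. **Margin framework** — exhaustive enumeration of marker subsets S,
   scored by the RMS discrepancy between the tumor trace **u**_T and the
   subset-mean trace **u**_S,

       S* = argmin f(S),   f(S) = ‖u_T − u_S‖₂ ,

   with the per-axis ITV_tracking margin of S* given by the worst-phase
   absolute discrepancy ‖u_T − u_S*‖ on each of the R-L, A-P and I-S axes.
5. **Log analysis** — per-fraction breathing amplitudes from time-stamped
   tracking logs (cycle segmentation at prominent maxima) and a paired
   two-tailed t-test against the planning 4D-CT amplitudes.
6. **Cohort tables** — machine-readable fixtures of the published
   17-patient / 42-lesion study results, with their summary statistics.

## Worked example

Track a moving seed in a synthetic phantom and pick the optimal marker
subset for a tumor synchronized with the superior marker:

```python
import fidmargin as fm

breathe = fm.MotionModel(kind="cos4", b=(0, 0, 10), tau=4.0)  # 10 mm I-S
spec = fm.PhantomSpec(
    grid_shape=(64, 64, 50), spacing_mm=(1, 1, 3),
    marker_specs=[fm.MarkerSpec(rest_center_mm=(32, 32, 45.5),
                                motion=breathe)],
)
volumes = fm.generate_phantom(spec)
markers = fm.detect_markers(volumes[0])
traj = fm.track_all(volumes, markers)[0]
z = traj.displacement_mm[:, 2]
print([float(round(v, 2)) for v in z])
print("peak-to-peak:", round(z.max() - z.min(), 2), "mm")
```

prints

```
[0.0, 1.75, 5.75, 8.75, 10.0, 10.25, 10.0, 8.75, 5.75, 1.75]
peak-to-peak: 10.25 mm
```

— the tracked I-S displacements per respiratory phase (mm, relative to
the 0% phase), within 0.25 mm of the analytic trace
b·(1 − cos⁴(πk/10)) = [0, 1.82, 5.72, 8.81, 9.91, 10, …], and the
recovered breathing amplitude.  Feeding the tracked trajectories and a
tumor trace to `select_optimal_subset` then yields S*, f(S*), and the
per-axis margin:

```python
gtv = fm.analytic_trace(breathe, 10, object_id="gtv")
res = fm.select_optimal_subset(
    gtv, [fm.MotionTrace("m1", traj.displacement_mm)])
print(res.optimal_subset, [float(round(m, 2)) for m in res.itv_tracking_margin_mm])
# ('m1',) [0.0, 0.0, 0.25]
```

The same pipeline is scriptable from a shell:

```sh
fidmargin simulate --config phantom.yaml --out vols/
fidmargin detect --phase0 vols/phase_00.nii.gz --out detections.json
fidmargin track --phases vols/ --detections detections.json --out traj.csv
fidmargin margins --gtv-trace gtv.csv --trajectories traj.csv --out margins.json
fidmargin reproduce-tables
```

`fidmargin reproduce-tables` prints the packaged cohort summaries:
73 fiducials and 42 lesions across 17 patients (median 5 markers per
patient), per-axis margin means 1.0 / 1.1 / 1.8 mm (SD 0.8 / 1.2 / 1.7),
41 of 42 lesions with all margins below 5 mm, and a mean GTV-to-marker
distance of 59.3 ± 24.6 mm.

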