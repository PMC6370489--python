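# braindyn

Simulating whole-brain resting-state dynamics with two delayed-coupling
brain network models and asking which dynamic rs-fMRI analysis methods
can tell them apart.

A brain network model (BNM) places one neural mass at each of 66
cortical regions and couples them through a structural connectome
`C` with per-pair conduction delays `τ_np = L_np / v` (v = 5.45 m/s,
mean delay calibrated to 11 ms). Two models are implemented:

- **Firing rate** (linear, noise-driven):
  `τ₀ dr_n/dt = −r_n + (k/c₁) Σ_p C_np r_p(t − τ_np) + σ n(t)`
  with τ₀ = 20 ms, σ = 2, default k = 0.9 (c₁ is the largest eigenvalue
  of C, so k < 1 is linearly stable).
- **Kuramoto** (delayed phase oscillators, run deterministically):
  `dθ_n/dt = ω_n + k Σ_p C_np sin(θ_p(t − τ_np) − θ_n)`
  with ω_n ~ N(60, 2) rad/s and default k = 13; the BOLD-driving
  observable is sin θ_n.

Neural activity is converted to BOLD with the Balloon-Windkessel
hemodynamic model, downsampled to TR = 0.72 s, and preprocessed with a
fixed chain (z-score → 0.01–0.25 Hz band-pass → global signal
regression → z-score) applied identically to every dataset. Five
analysis families then characterize the signals:

1. average functional connectivity (FC) and the (1/f)ⁿ spectral slope,
2. point-process coactivation (threshold crossings within ±3 TRs),
3. quasiperiodic-pattern (QPP) discovery by iterative template matching,
4. sliding-window FC + k-means brain states (k = 7, Manhattan distance),
5. recurrence quantification analysis (RR, mean diagonal length, entropy).

Everything external is synthesized: a generator builds a realistic
two-hemisphere modular connectome, and a surrogate resting-state
generator (switching covariance regimes, 1/f spectrum, planted
traveling motif) stands in for empirical scans.

Intended for computational neuroscientists who want a self-contained,
reproducible testbed for dynamic rs-fMRI metrics on controlled network
models.

## Worked example

```python
import braindyn as bd

conn = bd.generate_synthetic_connectome(66, seed=1)
print(f"{1e3 * conn.mean_connected_delay():.1f} ms")   # 11.0 ms

cfg = bd.SimulationConfig(model="firing_rate", dt=1e-3,
                          duration=120.0, discard=10.0, seed=1)
raw, proc = bd.run_bold_pipeline(conn, cfg)            # BOLD at TR 0.72 s
print(proc.values.shape)                               # (66, 152)

fc = bd.average_fc(proc)
co = bd.coactivation_matrix(proc, threshold=1.0)
m = bd.rqa_metrics(bd.recurrence_plot(proc, threshold=0.3))
print(f"RR = {m.rr:.3f}, L = {m.avg_diag_len:.2f}")    # RR = 0.179, L = 4.44
```

On this 120 s desk-scale run the coactivation matrix already correlates
r = 0.74 with average FC (r > 0.9 on full-length runs): coactivation
events carry essentially the same spatial information as average FC.
On 160 s runs the recurrence rate is 0.16 at default coupling, rising
to 0.27 at k = 0.999 and falling to 0.05 at k = 0.3 — recurrence grows
monotonically with global coupling.

The numbered drivers under `analysis/` walk through the full study at
desk scale (connectome → simulations → each metric family → the final
model-comparison report):

```bash
python analysis/01_build_connectome.py
python analysis/02_simulate_bold.py
...
python analysis/07_full_report.py
```

The final report ranks the two models per analysis family: the linear
firing-rate model tracks the spatial metrics (static FC) better, while
the Kuramoto model shows the richer temporal structure (more states,
higher diagonal entropy).

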