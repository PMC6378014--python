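# Methods

## Scope and model structure

`adipoflame` simulates a small, fixed sample of visceral adipose tissue
(default 1 μL) together with a resident macrophage pool, in discrete 8-hour
steps, for one subject under a prescribed daily caloric excess E (kcal/day,
possibly negative, with a weekly on/off mask). It couples four layers:

1. **Anthropometry** (closed forms): the subject's BMI sets the mean
   visceral adipocyte diameter through the saturating regression
   φ(BMI) = φ_c − λ·e^(−δ_d·BMI) (omental-depot estimate, applied to all
   visceral adipocytes); the Westerterp adult regression gives fat-free
   mass and hence the initial fat mass FM(0).
2. **Adipocyte dynamics** (stochastic agents): per-cell swelling draws and
   lipid increments, a volume floor at the baseline volume v₀, and
   recruitment of new cells once part of the population exceeds the
   critical volume v_c = (π/6)φ_c³.
3. **Inflammation** (phenomenological): lumped pro/anti cytokine pools
   with exponential decay, fed by supercritical adipocytes and polarized
   macrophages; saturating M0→M1/M2 switch probabilities with constant
   reversion.
4. **Observables**: daily records of weight, cell count and volume,
   supercritical fraction ζ, cytokines and M0/M1/M2 counts; onset
   detection and Kaplan–Meier curves over replicates.

Body weight is diagnostic, not dynamical: BW(t) = BW(0) + FM(0)/(1−δ_ffm) ·
(V(t)−V(0))/V(0). FFM is constant over a simulation; there is no
energy-expenditure adaptation, no adipocyte death, and no spatial
arrangement (the population is well-mixed).

## Parameters

| symbol | meaning | default | units |
|---|---|---|---|
| k₁, k₂ | swelling-probability shape | 4, 2 | — |
| k₃ | caloric-excess → lipid volume | 8·10⁻⁶ | μL·day/kcal |
| k₄ | volume-noise amplitude scale (sd = k₄·v₀) | 2·10⁻⁵ | — |
| k₅, k₆ | adipogenesis-probability shape | 5, −1 | — |
| v₀ | baseline adipocyte volume | 8.181·10⁻⁶ | μL |
| φ_c | critical diameter (male/female) | 120 / 123 | μm |
| s | energy-partition scale | 3.5376·10⁻⁴ | — |
| steps_per_day | 8-hour steps | 3 | 1/day |
| sim_volume | simulated tissue sample | 1 | μL |
| macrophages_per_ul | fixed pool size | 100 | cells/μL |
| s_adipo, s_M1, s_M2 | cytokine secretion rates | 1 each | a.u./cell/step |
| decay_per_step | cytokine decay fraction | 0.1 | 1/step |
| a, b | polarization switch ½(1+tanh(a·log₁₀(1+c)+b)) | 1, −6 | — |
| revert_prob | M1/M2 → M0 per step | 0.01 | — |
| onset threshold / persistence | inflammation-onset rule | 0.5 / 30 | — / days |

With k₆ = −1 the adipogenesis probability is exactly 0 at ζ = 0 (oddness
of tanh) and ≈ 0.880 at ζ = 1; the swelling probability is ≈ 0.982 at
v = v_c and ≈ 0.018 at 2v_c, which is what bounds cell growth.

## Energy partitioning (the central modelling choice)

k₃·E has units of μL/day. Distributing that amount to *each* cell every
step is dimensionally implausible (it exceeds v_c per step), so the
default reading is per-cell with a single dimensionless calibration
factor: every cell passing the swelling draw gains

    Δv = s · k₃ · E / steps_per_day  + η,   η ~ N(0, (k₄·v₀)²).

`s` (energy_partition_scale) was fixed **once** by secant iteration so
that the 42-day Diaz protocol (1506 kcal/day, 50 replicates) reproduces
the observed 7.6 kg mean gain, and is never retuned; the Tremblay
protocol is run with the same value as an out-of-sample check. An
alternative reading (`partition_mode="tissue"`) takes k₃·E as the daily
influx per μL of *current* tissue, split across the passing cells. It is
retained for comparison but makes the influx proportional to V(t), i.e.
unbounded exponential growth — usable on horizons of a few months only.

Two related choices keep the long-horizon dynamics bounded:

- **Noise amplitude.** The per-update noise is read as sd = k₄·v₀.
  Reading k₄·v₀ as a *variance* gives sd ≈ 1.6·v₀ per 8-hour step;
  measured over five years, the v₀ floor rectifies that diffusion into
  ≈ +2 kg/year and a full inflammatory state *at zero caloric excess*
  (every replicate "onsets" with E = 0), which contradicts both the
  zero-influx expectation and the graded onset behaviour the model
  exists to show. With the amplitude reading, E = 0 runs are inert
  (|ΔBW| < 10⁻³ kg over five years).
- **Recruitment rate.** One cell per time step per microliter of the
  *fixed simulated sample* (probability p_a per step). Tying the rate to
  the growing tissue volume instead would compound (recruits mature into
  volume, volume recruits more cells), again producing unbounded growth.

With these readings the model shows the intended two-phase weight
dynamics: a fast initial phase from swelling of the starting cells,
then a slower phase carried by newly recruited cells (e.g. at
E = 1500 kcal/day, mean rate ≈ 0.09 kg/day in months 0–2 vs
≈ 0.045 kg/day in years 2–5).

## Initial conditions

Initial cell count N₀ = round(sim_volume / volume(φ(BMI))) ≈ 2100 for the
Diaz subject. Diameters are drawn from a truncated normal centred on
φ(BMI) with CV 0.1 (a configuration knob), truncated to
[diameter(v₀), 2φ_c]; the spread is required for the supercritical
fraction to grow gradually rather than as a step. Subjects whose
predicted fat mass is ≤ 1 kg are rejected (`InfeasibleSubjectError`):
the weight map multiplies by FM(0), so a no-fat subject would silently
freeze the weight dynamics.

## Inflammation layer

The gene-regulatory network that in richer immune simulators decides
macrophage differentiation is deliberately out of scope; it is replaced by
the two-parameter switch above so that the observable claims — M1 drift,
its dose dependence in E, delayed emergence — live in a testable module
with a boundary where a network rule could drop in later. Macrophages are
tracked as aggregate M0/M1/M2 counts with binomial transitions; because
every cell in a state has the same transition probability this is
distributionally identical to simulating individual agents. The pool size
is fixed (no monocyte influx or death), so only fractions and orderings
are meaningful, not absolute counts.

Defaults were chosen so that (i) the resting state is quiet: at pro = 0
the switch probability is ½(1+tanh(−6)) ≈ 3·10⁻⁶ per step; (ii) the
equilibrium M1 fraction switch/(switch+revert) tracks the slowly rising
cytokine load over years rather than saturating within weeks; (iii) the
onset rule (M1 ≥ 0.5 for 30 days) separates excess-energy levels: with
50 replicates the median onset day is ≈ 324 / 172 / 118 / 93 for
E = 500 / 1000 / 1500 / 2000 kcal/day, and E = 0 never onsets. The M2
side is structurally symmetric but, with its only source being M2 cells
themselves, remains near zero — the counter-regulatory M2 expansion seen
in tissue data is *not* reproduced (see limitations).

The cytokine update applies decay to the previous concentration and then
adds the step's sources, so a constant source S settles at S/decay.

Year-end M1/M2 counts reported by `sweep` are trailing 30-day means,
which damps the binomial polarization noise of the 100-cell pool.

## Determinism and problem sizes

All randomness flows through one `numpy` generator per replicate;
replicate r uses seed base_seed + r, and a run re-launched from its JSON
manifest is bit-identical. The shipped analyses use the study scale —
50 replicates for the clinical fixtures (42 and 100 days) and for the
five-year sweeps over E ∈ {0, 500, 1000, 1500, 2000} kcal/day; a
five-year replicate of ~2–7·10³ cells takes well under a second, the full
sweep a few minutes.

## What the synthetic protocols do and do not show

The fixtures encode the published summary numbers of two overfeeding
studies (subject anthropometrics, daily excess, schedule, weight change);
no raw clinical data exist in the package. Passing the reproduction tests
shows the calibrated model is consistent with those two mean weight
gains, not that it generalises across subjects: the Tremblay check in
fact fails its ±2 kg band (simulated final ≈ 65.4 kg vs 68.4 kg
observed). Under the weight map, the gain is proportional to
FM(0)/(1−δ_ffm) ≈ 8.9 kg for that slim subject vs ≈ 20.9 kg for the Diaz
subject, so matching the observed 8.1 kg would require ~91% tissue-volume
growth from only 1.33× the on-protocol energy of the Diaz run — no
energy-proportional increment rule calibrated on the first study can
deliver that. The discrepancy is reported as-is; it marks the limit of
the single-calibration growth model, not a numerical defect.

## Known limitations

- Energy not stored as fat simply vanishes: there is no expenditure,
  lean-mass or adaptation model beyond the static regressions.
- Absolute macrophage counts are arbitrary (fixed 100-cell pool); only
  fractions/orderings are interpretable, and M2 counter-regulation is
  absent by construction.
- The onset definition (0.5 for 30 days) is a declared convention; onset
  *times* shift with it, although their ordering in E does not.
- The adult FFM regression and the omental diameter–BMI relation are used
  as printed; no pediatric or longitudinal validity is claimed.
- Hypocaloric diets only exercise the volume floor (cells shrink to v₀
  and stop); adipocyte death/turnover is out of scope.
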