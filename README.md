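# patchfrap

Quantitative analysis of FRAP and patch/FRAP experiments on membrane
receptors: a closed-form forward model of fluorescence recovery after
Gaussian-spot photobleaching, synthetic-data and particle-level binding
simulators, nonlinear curve fitting for the lateral diffusion coefficient
*D* and mobile fraction *R*_f, and the inference layer that converts
condition-wise mobility changes into stable/transient interaction calls and
complex fractions.

## The science

In a FRAP measurement a focused Gaussian laser beam (e⁻² radius *w*, here
0.77 µm) bleaches a fraction of the fluorophore-labeled receptors in a small
membrane spot; lateral diffusion of unbleached molecules refills the spot.
For pure 2-D diffusion the fractional fluorescence monitored with the same
beam is

    f(t) = Σₙ₌₀^∞ [(−K)ⁿ/n!] · [1 + n(1 + 2t/τ_D)]⁻¹,   τ_D = w²/(4D)

with bleach-depth parameter *K* (post-bleach fluorescence at the spot is
(1 − e⁻ᴷ)/K). A partially immobile population gives

    F(t) = F_pre · [(1 − R_f)·f(0) + R_f·f(t)]

so that the normalized recovery (F_∞ − F(0))/(F_pre − F(0)) equals the
mobile fraction *R*_f exactly. Fitting a measured curve yields per-cell
(*R*_f, *D*) estimates; curves recovering less than 20% constrain only
*R*_f and are excluded from *D* statistics.

In **patch/FRAP**, a co-expressed partner receptor is clustered and
immobilized by bivalent IgG ("patching") while the receptor of interest,
labeled only with monovalent Fab′ fragments, is measured by FRAP. Complexes
whose lifetime exceeds τ_D co-immobilize the labeled receptor — *R*_f drops
with no change in *D* (**stable**); complexes exchanging many times within
τ_D slow it instead — apparent *D* drops with no change in *R*_f
(**transient**). The stable-complex fraction is

    C = 100 · (R_f,free − R_f,CL) / R_f,free   [%]

computed on group means. Group contrasts use Student's *t* test (two
groups) or one-way ANOVA with Bonferroni-adjusted all-pairs post-hoc tests,
reported as mean ± SEM with the conventional significance stars.

The package also contains a particle-level reaction–diffusion Monte Carlo
(`simulate_binding_frap`): receptors diffuse in a periodic membrane patch
and bind/unbind immobile traps with first-order kinetics, a Gaussian-spot
bleach marks particles, and the Gaussian-weighted count of unbleached
particles is recorded. Sweeping k_off·τ_D across 1 reproduces the
stable→transient dichotomy quantitatively.

## Worked example

```sh
frap simulate --config configs/demo.yaml --seed 1 --out demo_out
frap fit --curves demo_out/curves.csv --w 0.77 --out demo_out/results.csv
frap infer --results demo_out/results.csv --contrasts configs/demo_contrasts.yaml \
           --alpha 0.05 --out demo_out/report
cat demo_out/report/summary.txt
```

The demo cohort simulates eight conditions (30 cells each) at published
group-mean mobile fractions for the ENG/NRP1/VEGFR2 receptor system. With
seed 1 the report reads:

```
ENG/NRP1 crosslink: stable — complex fraction 40% (Rf 65% -> 39%, p=9.1e-18 ****; D p=0.55 ns)
ENG/VEGFR2 crosslink: stable — complex fraction 31% (Rf 61% -> 42%, p=5.6e-12 ****; D p=0.72 ns)
VEGFR2/NRP1 crosslink: stable — complex fraction 40% (Rf 57% -> 34%, p=4.1e-20 ****; D p=0.68 ns)
VEGFR2/NRP1 crosslink + ENG coexpression: stable — complex fraction 68% (Rf 57% -> 18%, p=1e-35 ****; D p=0.022 *)
VEGF-A effect on crosslinked ENG/NRP1: ligand contrast Rf 39% -> 26%, p=3.7e-14 ****
```

Each line is one free-vs-crosslinked contrast: the interaction call, the
stable-complex fraction from the fitted group means, the *R*_f change with
its Bonferroni/t-test p-value, and the corresponding *D* contrast. IgG
immobilization of the partner pulls down a third to two thirds of the
labeled receptor's mobile pool while *D* stays put — the signature of
pre-formed stable complexes — and coexpressing untagged ENG deepens the
NRP1/VEGFR2 co-immobilization (68%), consistent with a bridging role.

Per-cell estimates live in `demo_out/results.csv` (cell_id, condition,
Rf_hat, se_Rf, D_hat_um2_per_s, se_D, recovery_pct, d_reliable, converged,
rss).

## Layout

- `src/patchfrap/forward_model.py` — recovery series, beam/mobility types
- `src/patchfrap/synthetic.py` — noisy-curve generator, cohort generator, binding Monte Carlo
- `src/patchfrap/fitting.py` — normalization, K estimation, (R_f, D) regression, QC
- `src/patchfrap/inference.py` — complex fraction, group statistics, interaction calls
- `src/patchfrap/cli.py` — `frap simulate | fit | infer`
- `docs/methods.md` — model assumptions, parameter choices, numerical details
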