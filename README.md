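# mannoload

Quantitative analysis for macrophage-targeted drug-carrier systems:
receptor-binding titrations, drug-loading equilibria and cellular
uptake/efflux partitioning, with ground-truth-known synthetic data for
every stage.

## The problem

Delivering antibiotics to macrophages hinges on three measurable
quantities. First, how strongly a mannosylated carrier binds the
macrophage mannose receptor (or its standard laboratory surrogate, the
lectin concanavalin A) — determined by spectroscopic titration and Hill
analysis. Second, how much drug (e.g. the fluoroquinolone moxifloxacin)
the carrier loads — a mass-action equilibrium yielding the entrapment
efficiency (EE) and loading capacity (LC). Third, how the drug
distributes between solution, the bacterial cell wall and the cell
interior over time, and how an efflux-inhibiting adjuvant such as
eugenol changes that distribution. `mannoload` implements this chain
for experimentalists who have titration tables, FTIR spectra or
compartment concentration tables and want the derived constants and
statistics — reproducibly, with diagnostics, from Python or the shell.

## Models

**Binding.** For R + nL ⇌ R·L·n with Kd = [L]ⁿ[R]/[R·Lₙ], any signal ξ
linear in the bound fraction follows the Hill isotherm
ξ = ξ₀ + (ξ∞−ξ₀)·Lⁿ/(Lⁿ+Kⁿ). Estimation is two-stage: a nonlinear fit
supplies the asymptotes, then ordinary least squares on the Hill plot
lg(θ/(1−θ)) = n·lg[L] − lg Kd gives n (slope) and −lg Kd (intercept)
with standard errors. Kd = Kⁿ carries units Mⁿ.

**Loading.** A carrier with N equivalent sites at total C_L and drug at
total C_M obeys Kd·C_b = (C_M−C_b)(N·C_L−C_b); the physical (smaller)
quadratic root gives the bound concentration, then
EE = 100·C_b/C_M and LC = 100·N·m_drug/m_carrier.

**Uptake.** Three-compartment statistics (mass balance, absorbed
fractions, peak accumulation, adjuvant enhancement, retention ratio) on
measured tables, plus a closed first-order kinetic model
solution ⇌ wall → interior → solution with delayed efflux inhibition
for simulation and rate fitting.

The signal-extraction chain for FTIR titrations (blank subtraction,
baseline correction, min–max normalization, Savitzky–Golay smoothing
and second differentiation, peak picking with sub-grid refinement) is
included, so ξ can be read directly from raw spectra. See
`docs/methods.md` for assumptions, defaults and limitations.

## Worked example

Simulate a titration with known truth (n = 1.2, −lg Kd = 6.0, 1% noise)
and fit it back:

```sh
$ cat demo.yaml
titration:
  n: 1.2
  neg_lg_Kd: 6.0
  noise_sd: 0.01

$ mannoload simulate-titration --config demo.yaml --seed 1 --out titration.csv
wrote 12 titration points to titration.csv

$ mannoload fit-binding --titration titration.csv
n = 1.150 ± 0.010   -lg Kd = 5.698 ± 0.053   R² = 0.99979  (5 points)
```

The fit reports the Hill stoichiometry and −lg Kd with regression
standard errors; the quoted uncertainties are conditional on the fitted
asymptotes, so scatter across replicates is somewhat larger (at this
noise level, replicate means land within ~0.1 of the truth).

Solve a loading system — a 2.1 kDa cyclodextrin carrier
(−lg Kd = 4.0, one site) loading 1 mM moxifloxacin at 0.1 mM carrier:

```sh
$ mannoload load-calc --neg-lg-kd 4.0 --n-sites 1 --m-ligand 2100
C_bound = 9.0098e-05 M
EE = 9.0 %
LC = 19.1 %
```

i.e. 9% of the drug is entrapped and the carrier holds 19% of its own
mass in drug. The same numbers are available from Python:

```python
from mannoload import LoadingSystem, entrapment_efficiency

sys = LoadingSystem.from_neg_lg_kd(4.0, N=1, c_ligand_total=1e-4,
                                   c_drug_total=1e-3)
entrapment_efficiency(sys)   # 9.0098...
```

Simulate the two arms of an uptake experiment and compare them:

```sh
$ mannoload simulate-uptake --out control.csv
$ mannoload simulate-uptake --with-adjuvant --out treated.csv
$ mannoload uptake-report --table treated.csv --control control.csv
MF: peak absorbed 21.8 at 840 min
  t=     0 min  recovery  100.0%
  ...
enhancement vs control: 338.1%
```

Every row recovers 100% of the dose (the synthetic model conserves
mass exactly); the adjuvant arm accumulates more drug because efflux is
suppressed after its onset. `mannoload run-all --config ... --seed ...`
chains simulation, spectral preprocessing, fitting, loading and uptake
reporting into one reproducible run whose outputs carry the config hash
and seed.

A bundled measured dataset (`mannoload.datasets`) provides the
published time-resolved moxifloxacin/eugenol distribution in
*B. subtilis* suspensions for the uptake statistics.

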