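# crnpf

Stationary analysis of stochastically modeled chemical reaction networks
with generalized product-form kinetics.

For a network whose species can be partitioned by the per-species gcd of
source stoichiometries (`alpha_i`), and whose intensity functions factor as

    lambda_k(x) = kappa_k * prod_i prod_{j=0}^{nu_ki/alpha_i - 1} theta_i(x_i - j*alpha_i),

the stationary measure is of product form,

    pi(x) ~ prod_i c_i^{x_i} / prod_{j=0}^{floor(x_i/alpha_i)-1} theta_i(x_i - j*alpha_i),

where `c` is a complex-balanced equilibrium of the associated deterministic
mass-action system. This package implements that characterization
end-to-end, together with the machinery needed to validate it and to use it
in multiscale (averaging) reductions:

- **`crnpf.network`** — network representation, file format, structural
  report (complexes, linkage classes, weak reversibility, deficiency,
  exact integer conservation laws) and the alpha-partition.
- **`crnpf.kinetics`** — mass-action, theta-product and alpha-theta-product
  intensities; zero-pattern/divisibility validation; the recursive
  phi-factorization `theta(z) = phi(z)...phi(z-alpha+1)` and its checks.
- **`crnpf.equilibrium`** — complex-balance residuals and a damped Newton
  solver in log-concentrations (optionally on an affine slice).
- **`crnpf.product_form`** — state classes (box + linear invariants +
  residue constraints), log-space measure evaluation, normalization,
  marginals and moments.
- **`crnpf.exact`** — truncated-generator construction, sparse stationary
  solves, master-equation balance residuals, Gillespie simulation,
  distribution distances.
- **`crnpf.averaging`** — quasi-equilibrium and constrained reductions of
  the fast dimerization benchmark, effective slow-variable rates, and the
  full-vs-reduced comparison pipeline.
- **`crnpf.fixtures`** — the benchmark systems as built-in fixtures plus
  seeded random deficiency-zero networks and random theta tables for
  property-based testing.

## CLI

```sh
crnpf fixtures list
crnpf fixtures export constrained_system18 sys18.json
crnpf analyze sys18.json
crnpf equilibrium sys18.json --constrain "S1+2*S2=1"
crnpf stationary sys18.json --class "S1+2*S2=300" --box 300,150 \
      --constrain "S1+2*S2=1" --out dist.tsv
crnpf solve-exact sys18.json --class "S1+2*S2=300" --box 300,150 --out exact.tsv
crnpf simulate sys18.json --x0 300,0 --t-end 10 --seed 1 --out occ.tsv
crnpf compare-averaging --params k1=1,k2=100,k3=1500,k4=30 --s 300 \
      --box 500,350 --out report.json
```

Distributions are TSV (state coordinates, probability, log-weight) with a
JSON metadata header line; reports are JSON embedding the tool version,
seed and a config hash.

## Notes

- All measure arithmetic is in log space (extended precision for the
  accumulated log-denominators), so boxes up to ~1e3 per coordinate are
  handled without overflow.
- Truncation is reflecting-by-dropping: transitions leaving the enumerated
  state set are removed; the boundary-shell mass is reported with every
  normalized distribution so truncation quality is always visible.
- The sparse stationary solve replaces one balance equation of the adjoint
  generator with the normalization row and uses a direct LU factorization;
  the state space must contain exactly one closed communicating class
  (restrict by conserved quantity and/or parity otherwise).
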