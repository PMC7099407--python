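# minicrispr

Evolutionary game analysis of virus-encoded mini-CRISPR arrays.

Some bacterial and archaeal viruses carry **mini-CRISPR arrays** — one or
two spacers without *cas* genes — that, together with the host's Cas
machinery, target a competing virus during coinfection of the same host
cell. Carrying such an array is a weapon with a price: it imposes a
fitness cost *c* on its carrier (e.g. through imperfect self-targeting
and primed adaptation) and pays off only in the fraction *p* of
infections that are coinfections with the rival. This package implements
the two-virus evolutionary game that formalises this trade-off, for
theorists and modellers studying interviral conflict, superinfection
exclusion, and the ecology of CRISPR-mediated arms races.

## The model

Two virus strains A and B compete; each may carry a spacer against the
other. With single-infection productivity normalised to 1, the mean
productivity of strain A (coinfection probability `p = p_B|A`) is

|                    | B targets A            | B does not target    |
|--------------------|------------------------|----------------------|
| **A targets B**    | `(1-c)(1-p+qp)`        | `1-c`                |
| **A does not**     | `1-p`                  | `1-(1-w)p`           |

where `w` is A's yield in an untargeted mixed coinfection and `q` the
probability that A arrives first (and hence wins) under mutual
targeting. The spacer-carrier fractions `x_A, x_B` follow replicator
dynamics, which reduce to

```
dx_A/dt = x_A (1 - x_A) (a + b x_B),     a  = (1-w_A) p_B|A - c_A,
dx_B/dt = x_B (1 - x_B) (a' + b' x_A),   b  = p_B|A (q_A - q_A c_A + c_A + w_A - 1),
```

(and primed analogues for strain B). Two critical coinfection
probabilities per strain decide everything: `P* = c/(1-w)` (targeting
pays against a non-targeting rival) and `P** = c/(q - qc + c)` (against
a targeting rival). Comparing each strain's `p` with its `(P*, P**)`
yields the regimes: **no targeting**, **unidirectional targeting**
(either way), **mutual targeting**, **cyclic polymorphism** (closed
orbits around an interior neutral equilibrium), and two **bistable**
regions. The package also covers the provirus-pair payoff variant
(`P* = 2c/(1+c-2w)` at `q = 1/2`), early/late superinfection-exclusion
cases, lytic–temperate specialisations (`q_L = 0, q_T = 1`), a
spacer-loss (replicator-mutator) extension in which populations become
polymorphic with carrier fraction `x = 1 - d/s`, and the pairwise
decomposition of multi-virus competition under linear cost.

## Worked example

The packaged example `src/minicrispr/examples/cyclic.yaml` sets
`c = 0.1, w_A = 0.8, w_B = 0.5, q_A = 0.5, q_B = 0.2, p_B|A = 0.2,
p_A|B = 0.3`:

```
$ minicrispr classify --config src/minicrispr/examples/cyclic.yaml
{
  "label": "cyclic",
  "P_star_A": 0.5000000000000001,
  "P_star_star_A": 0.18181818181818182,
  "P_star_B": 0.2,
  "P_star_star_B": 0.35714285714285715,
  "stable_corners": [],
  "interior_equilibrium": [
    0.7575757575757576,
    0.8571428571428571
  ]
}
```

Strain A's coinfection probability (0.2) lies between its thresholds in
one order (`P** < p < P*`) and strain B's (0.3) in the opposite order
(`P* < p < P**`), so no corner of the unit square is stable: spacer
frequencies orbit the neutral equilibrium at `x_A ≈ 0.758,
x_B ≈ 0.857` forever — subpopulations with and without arrays alternate
cyclically. Integrating from `(0.5, 0.5)`,

```
$ minicrispr simulate --config src/minicrispr/examples/cyclic.yaml \
      --x0 0.5,0.5 --t-max 1000 --out traj.tsv
{
  "terminal_state": "cycling",
  ...
}
```

confirms a closed orbit (the first integral of the reduced system
drifts by ~2e-9 over a thousand generations). Other subcommands:
`sweep` tabulates the regime over a grid of coinfection probabilities
(a phase map), `scenario` resolves lifestyle presets such as
`lytic_lytic`, `provirus_provirus` or `lytic_provirus_late_SE`, and
`fixtures` generates seeded random parameter sets.

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the package's core computations from scratch: agreement of the
threshold-sign classification with the corner-stability oracle and with
numerical basin classification on seeded random draws, the reference
cyclic orbit and the drift of its conserved quantity, and
replicator-mutator equilibria against the loss-selection balance
`x = 1 - d/s`. Progress is logged to standard error and the summary
JSON is written to `--out`.

See `docs/methods.md` for the model assumptions, parameter conventions,
numerical choices and known limitations.
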