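# nhejsim

Stochastic simulation of DNA double-strand-break (DSB) fragment rejoining
through the Ku-dependent non-homologous end-joining (NHEJ) pathway.

Ionising radiation shatters chromosomal DNA into fragments. The first step
of NHEJ is recruitment of the Ku70/Ku80 heterodimer to a free fragment end,
and Ku needs physical room on the DNA: a fragment shorter than a minimum
length `L_min` (default 20 bp) cannot bind Ku at all and is irreparable by
this pathway, a fragment between `L_min` and a critical length `L_c`
(default 42 bp) can hold only one Ku at a time, and a fragment of at least
`L_c` can hold one per end. High-LET radiation (Fe ions, alpha particles)
clusters its damage and produces far more short fragments than low-LET
gamma rays at the same dose — and this package exists to quantify how that
length spectrum alone changes repair kinetics.

## Model

The state is a multiset of fragments with per-end occupancy. Three
irreversible reaction classes act on it, simulated exactly with Gillespie's
direct method:

| reaction | propensity | effect |
|---|---|---|
| recruitment | `k_f·n_E / V` per FREE end | end becomes BOUND |
| joining | `k_j / V` per pair of BOUND ends on distinct fragments | fragments `F_n + F_m → F_{n+m}` |
| release | `k_r` per residue token | blocked end(s) become FREE |

Joining leaves a Ku *residue* at the junction whenever a partner is short:
a short+short join blocks both ends of the product (residue pair `R`), a
short+long join blocks only the short partner's side (`r`), and a long+long
join leaves no obstruction. Blocked ends cannot recruit until the residue
is released at rate `k_r` — this is what makes short-fragment repair slow.
`V` is the nuclear volume; both second-order reactions scale as `1/V`. All
times and volumes are in arbitrary consistent units (results are
unit-covariant).

The **rejoining time** is the elapsed time from the initial `M0` countable
fragments down to a single fragment. For systems of up to a few fragments
the package also solves the underlying continuous-time Markov chain
exactly (mean first-passage time to the absorbed state), which validates
the stochastic engine; for two one-site fragments the closed form is
`3/(2a) + 1/b` with `a = k_f·n_E/V`, `b = k_j/V`.

## Worked example

```sh
python examples/02_exact_oracle.py
```

```
two-short closed form 3/(2a) + 1/b = 2.5000

fixture                        exact  SSA mean      SE
two short (30, 30)            2.5000    2.4896  0.0148
short + long (30, 100)        1.8333    1.8240  0.0108
two long (100, 100)           1.2963    1.2884  0.0070
three mixed (30, 30, 100)     4.7064    4.8165  0.0591
```

Each row is one small fragment system: the exact mean rejoining time from
the Markov-chain solver, and the stochastic mean over 10,000 Gillespie
replicates with its standard error — every stochastic mean lands within
about 3 standard errors of the exact value. Two 30-bp fragments need two
recruitments and one join (`1/2 + 1 + 1 = 2.5` at unit rates); adding a
third short fragment nearly doubles the time because the short+short
product is blocked until its residue is released.

The other examples sweep the impact factors and run the radiation presets:

```sh
python examples/03_impact_factors.py   # volume, release rate, L_c jump
python examples/04_radiation_kinetics.py   # Fe-ion vs gamma kinetics
```

The length sweep shows the critical-length jump — 20 fragments of 42 bp
rejoin in a mean time of 3.5, but at 41 bp (one Ku at a time, every join
release-limited) the mean is 31.5, a factor of ~9. The kinetics example
prints the mean fraction of fragments remaining, `P(t)`: the Fe-ion preset
(30% short + 10% irreparable fragments) plateaus at 0.108 while the
gamma-ray preset (3% short + 1% irreparable) decays to 0.020 — the biphasic,
incomplete repair seen in high-LET foci experiments, produced purely by the
fragment-length spectrum.

A thin CLI wraps the same library calls, e.g.:

```sh
nhejsim gen-dist --preset fe_ion --m0 200 --seed 1 --out fe.tsv
nhejsim simulate --dist fe.tsv --seed 1 --out traj.tsv
nhejsim oracle --fixture two-short --a 1 --b 1
```

Every output table is accompanied by a `*.config.yaml` echo from which the
run can be regenerated exactly; a master seed is mandatory for all
stochastic commands.

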