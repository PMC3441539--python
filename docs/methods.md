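# Methods

## The model

`nhejsim` simulates the rejoining of radiation-induced DNA fragments by the
Ku-dependent NHEJ pathway, reduced to the Ku binding step: later NHEJ
factors (DNA-PKcs, XRCC4/LigIV, XLF) and competing pathways (homologous
recombination, Ku-independent backup NHEJ) are deliberately outside the
model. A fragment of length `n` bp exposes 0, 1 or 2 tracked Ku-binding
ends:

* `n < L_min` — no binding site; the fragment is irreparable here and
  participates in nothing;
* `L_min <= n < L_c` — one site: the fragment can hold one Ku at a time;
* `n >= L_c` — two sites, one per end.

Three reaction classes, all irreversible:

1. **Recruitment.** A FREE end binds Ku at propensity `k_f·n_E/V`. Ku is
   abundant, so the copy number `n_E` is constant; irreversibility is the
   limit of Ku's high affinity and slow dissociation.
2. **Joining.** Any pair of BOUND ends on two *distinct* fragments ligates
   at propensity `k_j/V` (so a fragment pair with `b_i` and `b_j` bound
   ends carries total propensity `(k_j/V)·b_i·b_j`). Circularisation (a
   fragment joining its own two ends) is disallowed. The product has the
   summed length and the capacity that length dictates. Residues:
   * short+short → one residue pair `R` blocking every tracked end of the
     product (if the product is still below `L_c` it has a single tracked
     end, which is blocked — after release it still has only one usable
     end);
   * short+long → a one-sided residue `r` blocking the product's end on the
     short partner's side. The junction sits within `L_c` of the short
     side's distal end only, which is why the short side is the blocked
     one; the long partner's non-joining end keeps its status (including a
     surviving `r` of its own);
   * long+long → no obstruction; both non-joining end statuses carry over.
3. **Release.** Each residue token is removed at rate `k_r`, freeing every
   end it blocks in a single event (an `R` is one residue *pair* with one
   release reaction).

The state (fragment multiset + residue tokens) conserves total base pairs
under every update, and the fragment count falls by exactly one per join.
The **rejoining time** of a run starting from `M0` countable fragments is
the time of the `(M0−1)`-th join; residue release after the final join is
deliberately excluded, matching the fragment-count-based definition.

## Parameters

| parameter | meaning | default | why |
|---|---|---|---|
| `k_f` | recruitment rate constant (volume/time) | 1.0 | sets the time unit; absolute constants are not identifiable from foci-style data, so all results are unit-covariant |
| `n_E` | Ku copy number | 1 | pseudo-first-order convention: fold the concentration into `k_f` |
| `k_j` | joining rate constant (volume/time) | 1.0 | same footing as recruitment |
| `k_r` | residue release rate (1/time) | 0.1 | release requires ubiquitylation or Mre11/Ctp1 nuclease action and is the slow step; an order of magnitude below binding makes the release-limited phase visible at default settings |
| `L_min` | minimum length to hold Ku | 20 bp | ~14 bp of Ku footprint plus translocation; ~20 bp needed for efficient binding |
| `L_c` | critical length for two Ku | 42 bp | a 42-bp duplex binds two Ku heterodimers, one per end |
| `V` | nuclear volume (arbitrary) | 1.0 | second-order propensities scale as 1/V |

All are config-exposed; the two thresholds are biological constants in
normal use, the rates are free parameters.

## Simulation

The engine is Gillespie's direct method: waiting time `~ Exp(a0)` with `a0`
the total propensity, then a single uniform scanned against the cumulative
propensity in a fixed channel order — RECRUIT channels by (fragment id,
end index), JOIN channels by fragment-id pair `(i, j)` with `i < j`,
RELEASE channels by token id. The implementation evaluates that scan in
O(n) per step with per-fragment bound-end suffix sums rather than
materialising the O(n²) JOIN list; a test asserts the fast scan selects
the identical channel as a literal cumulative scan over the enumerated
list for the same uniform draw. The elementary ends used by a JOIN are the
lowest-indexed BOUND end of each partner; when both ends of a fragment are
bound the two choices are exchangeable, so the tie-break does not affect
the dynamics.

Reproducibility: a run is fully determined by (distribution, parameters,
seed); replicate `i` of an ensemble with master seed `s` uses a generator
seeded from `SeedSequence((s, i))`, and sweep/surface points extend the
tuple, so tables are independent of execution order and identical across
runs.

## Exact oracle

For up to 4 fragments the reachable state space is enumerated
breadth-first using the same update rules and propensities as the engine.
States are canonicalised as the *sorted* tuple of fragment encodings
`(length, end codes)` — fragments unordered, ends ordered within a
fragment — with codes F/B for free/bound and R/r for ends blocked by the
two residue types (all `R` ends of a fragment share one token; each `r`
end carries its own). The mean rejoining time is the mean first-passage
time to the absorbing set (countable-fragment count 1), solved as a dense
linear system with a verified residual below 1e-10. The two-short closed
form `3/(2a) + 1/b`, a hand-derived short+long value of `11/6` and a
two-long value of `35/27` (at unit propensities) anchor the solver in the
tests, and the stochastic engine is required to agree with the oracle
within 3 standard errors on every fixture.

## Synthetic initial distributions

Real fragment spectra depend on radiation track structure, which is out of
scope; the generators emulate its *summary statistics* only:

* `fixed_length` — all fragments one length (the mean-length experiments);
* `uniform_random` — distinct lengths and counts uniform on given ranges;
* `two_class` — a short fraction in `[L_min, L_c)` and a long remainder in
  `[L_c, 3000]` bp; presets `fe_ion` (30% short) and `gamma` (3% short)
  encode the two-class spectra for 1 Gy of each radiation quality;
* `fraction_pair` — prescribed fractions `(q1, q2)` of the two short
  sub-ranges split at `ceil(L_c/2) = 21` bp, the point below which even a
  pairwise join cannot reach `L_c`;
* `add_irreparable` — appends sub-`L_min` spectators for comparison-mode
  kinetics. Their preset fractions (10% Fe-like, 1% gamma-like) are model
  choices that keep the ~10× high/low-LET ratio of the short fractions;
  the true irreparable yield is not experimentally resolved.

Class counts are apportioned deterministically (half-up rounding,
remainder to the long class) so preset fractions are exact; only lengths
are sampled. What passing tests on these inputs do *not* show: anything
about correlated fragment positions along a chromosome, complex
(dirty-ended) DSBs, dose-rate effects, or the absolute time scale of real
repair — the model speaks to how the *length spectrum* reshapes kinetics,
not to calendar minutes.

## Ensembles and problem sizes

Ensemble experiments (replicate rejoining-time statistics with min/max
fluctuation bars, sweeps over `V`, `k_r`, `M0` and fixed length, the
`T(q1, q2)` surface, and mean fraction-remaining kinetics
`P(t) = ⟨count(t)⟩/count(0)`) are deterministic functions of their master
seed. Default problem sizes in the tests and examples — 20-fragment
populations, 150–500 replicates per sweep point, a 3×3 fraction grid with
10 distributions × 50 replicates, 200-replicate kinetics at `M0 = 100` —
are the package's chosen working scale; every routine accepts larger
values, and statistical checks use 3-standard-error bands throughout. The
kinetics normalisation is the plain count ratio `P(t)`; no foci-calibration
offset or rescaling is applied.

## Numerical and design notes

* State updates mutate in place (the oracle copies explicitly); ensembles
  of 10⁴ replicates make functional copies prohibitive.
* `simulate` stops at completion (countable count 1), at the horizon
  `t_max` (the event that would cross it is discarded), or — only possible
  when no channel is open with more than one countable fragment — reports
  a stalled state distinctly, which in default mode signals a bug rather
  than a valid outcome.
* Floating-point overrun at the end of the cumulative scan falls back to
  the last channel of the active class (probability ~0, but deterministic).
* Degenerate inputs: a single-fragment distribution completes at time 0
  with no events; empty distributions, non-integer lengths, fractions
  outside the simplex and ranges violating the class definitions are
  rejected with named errors.

## Limitations

Irreversible binding is an approximation of reversible Ku binding with a
small off-rate; it preserves the qualitative kinetics but not necessarily
quantitative profiles. The model has one generic repair protein and no
spatial structure: all fragment pairs join at the same rate regardless of
genomic distance. Exact solutions are limited to ~4 fragments by
combinatorial growth — beyond that, the stochastic engine *is* the method.
Absolute rates are not calibrated to data; only ratios and orderings are
meaningful.
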