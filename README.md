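# metanet

Persistence analysis of age-structured metapopulations on dispersal
networks — for ecologists and conservation planners who need to know
whether a set of patch populations coupled by juvenile dispersal (marine
larvae, invertebrates, plants, fish) can sustain itself, and which dispersal
routes actually matter.

## The model

Each patch holds an age-structured population projected yearly by a Leslie
matrix: survival probabilities `p_k` (age `k−1` to `k`) on the subdiagonal,
fertilities `f_k` in the first row, with a fraction `σ` of juveniles
self-recruiting to their natal patch. The reproductive number of one patch is

```
R = Σ_k f_k l_k,   l_1 = 1,  l_k = p_2 ··· p_k
```

and an isolated patch grows iff `σR > 1` (a *source*; otherwise a *sink*).

`n` patches are coupled through a connectivity matrix `C`, where `C[i,j]` is
the proportion of patch-`j` juveniles recruiting to patch `i`. The
metapopulation grows iff the **persistence parameter**

```
χ = R · ρ(C)  >  1
```

with `ρ` the spectral radius. Under the uniform dispersal scheme
`C = σI + εA` (adjacency `A`, migration intensity `ε` per link) this becomes

```
χ = R (σ + ε ρ(A))
```

so network topology enters through a single number, `ρ(A)`. The package
computes χ three equivalent ways (closed form, `m×m` stability matrix
`S + ρ(C)F`, full `nm×nm` eigensolve), decomposes networks into the
**cyclic components** (nontrivial strongly connected components) that alone
determine `ρ(A)`, identifies **lonely links** (edges on no directed cycle —
removable without any effect on persistence) and **critical links** (whose
removal collapses `ρ(A)`), estimates `ρ(A)` from degree statistics
(`p(n−1)` for dense Erdős–Rényi, `⟨d⟩(1+CV²)` for heterogeneous degree
distributions), and bounds persistence for *nonidentical* patches by
envelope (dominating/subordinate) patch constructions.

## Worked example

A two-age-class demography with `f = (0, 4)`, `p_2 = 0.5`, `σ = 0.3`
(`demog.json`: `{"m": 2, "survival": [0.5], "fertility": [0.0, 4.0],
"sigma": 0.3}`) is a sink on its own:

```
$ metanet patch --config demog.json
{ "R": 2.0, "chi": 0.6, "label": "sink" }
```

`R = 2` juveniles per recruit, but only `σR = 0.6 < 1` return home. Put ten
such patches on a ring (every patch two neighbours, `ρ(A) = 2`) with
migration `ε = 0.3`:

```
$ metanet generate regular --n 10 --q 2 --seed 1 --out ring.tsv
$ metanet analyze ring.tsv --config demog.json --sigma 0.3 --epsilon 0.3
{
  "R": 2.0,
  "chi": 1.8,
  "lambda_max": 1.3416407865,
  "rho_A": 2.0,
  "rho_C": 0.9,
  "verdict": "persisting",
  "patch_fates": ["persisting", ...]
}
```

`χ = R(σ + ερ(A)) = 2·(0.3 + 0.3·2) = 1.8 > 1`: a network of pure sinks is
pulled over the threshold by subsidy recruitment circulating around the
cycle — the dominant eigenvalue `λmax ≈ 1.342` of the full 20-dimensional
system confirms ~34% annual growth.

Cycle structure of a two-component example network (a simple 3-cycle, a
complex 6-patch component of intersecting cycles, nine patches attached
only by lonely links):

```
$ metanet fixture fig4_two_components --seed 0 --outdir fig4
$ metanet critical-links fig4/edges.tsv --top 2
{
  "ranking": [
    { "delta_rho": 0.442249570307, "link": [5, 6] },
    { "delta_rho": 0.442249570307, "link": [6, 7] }
  ]
}
```

Cutting either critical link drops `ρ(A)` from ≈1.442 to exactly 1 (only
non-intersecting simple cycles remain); cutting any lonely link changes
nothing (`delta_rho = 0`). Other subcommands: `cycles` (component
decomposition report), `simulate` (trajectory CSV + fitted growth factor),
`bounds` (nonidentical-patch envelope bounds, per-patch records via
`--patches patches.json`), `fixture` (worked-example networks).

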