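# Methods

This note records the scoring model, the default parameters and why they
were chosen, the numerical conventions, what the synthetic fixtures do and
do not emulate, and the known limitations.

## Secondary-structure representation

A structure is a sequence over `ACGUN&` plus a set of base pairs `(i, j)`,
1-based, `i < j`, with no position in two pairs (base triples are rejected,
or optionally dropped first-come-first-kept with `drop_conflicts`). Parsers
and writers exist for dot-bracket (with `()[]{}<>` and `Aa…Zz` tiers for
pseudoknots), CT, and BPSEQ. Two arcs cross — form a pseudoknot — when
`i < k < j < l`.

**Substructures.** A substructure is a maximal run of stacked base pairs:
sorting pairs by their 5′ position, successive pairs `(i, j)`, `(i′, j′)`
are chained when `i < i′`, `j′ < j`, and the unpaired gap on each side is at
most `max_internal_unpaired` (default **2**: absorbs 1–2 nt bulges and small
interior loops, which are ubiquitous inside what is biologically one helix,
while still splitting at multiloops and larger loops). The *simplified
diagram* is the ordered list of substructures plus the crossing relation
between them.

**Environments.** Each base pair gets an (inner, outer) environment tuple
drawn from {stem, hairpin, bulge, interior, multiloop, pseudoknot}; the
exterior loop is labeled multiloop, and a pair directly crossed by another
arc is labeled pseudoknot.

## Scoring

Substitution scores come from the bundled RIBOSUM85-60 tables: a symmetric
4×4 single-nucleotide matrix `Rs`, a symmetric 16×16 base-pair matrix `Rp`,
and background frequencies (A/U 0.27, G/C 0.23). `N` scores as the
background-weighted average; the `&` chain separator can never be matched
(−∞) and is gapped for free.

**Pair score.** Aligning query pair `q` to template pair `t` scores
`Rp(q, t)` plus an environment bonus: **0** if the environment tuples
differ, **1** if both are (stem, stem), **3** if equal otherwise. The stem
case gets the small bonus because stacked-stem context is the default and
carries little signal; agreement in a rarer environment (hairpin closing
pair, multiloop pair, pseudoknot) is stronger evidence of equivalent
structural roles.

**Sequence profile.** Rows of the query MSA are filtered to pairwise
identity ≤ 0.8 against the query (removes redundancy) and coverage ≥ 0.75
of the query length (removes fragments); the query row always stays. With
`f(i, ·)` the observed column frequencies, `d` the count of non-query
letters in the column, and `p(q_i)` the query letter's background, the
profile is the pseudocount log-odds

    F(i, k) = log2[ (d·f(i,k) + 2·p(q_i)·g(i,k)) / (p(q_i)·(d + 2)) ],
    g(i, k) = Σ_m 2^(0.4·Rs(k,m)) · f(i,m).

For a single-row MSA this collapses exactly to `0.4·Rs(q_i, ·)` (checked to
1e−9 in tests), so shallow alignments degrade gracefully to the
substitution matrix. The profile is used only when `Neff` (rows surviving
the filter) is at least **5** — below that, column statistics are too noisy
to beat the matrix. All-gap columns fall back to the `0.4·Rs` row.

**Gaps.** Affine: a length-L gap costs `open + (L−1)·extend`, defaults
**open 3, extend 1** — on the RIBOSUM score scale (best single match 2.22)
this makes one gap cheaper than two mismatches but discourages scattering.
Terminal gaps are free in the final alignment (the query may cover only
part of a template and vice versa) but *not* in the substructure stage,
where both halves should be matched end to end. With a usable profile,
query-side gap penalties are multiplied by `max(0.1, 1 − gap_ratio(i))`:
columns that are mostly gaps in the family are cheap to gap in the
alignment too.

## Stage 1: substructure matching

For every query/template substructure pair, a global affine-gap DP aligns
the 5′ halves (each aligned pair of 5′ positions induces the corresponding
3′ pair), with the pair score above as the cell score; negative totals are
floored at 0 ("no match" is always available). The matcher then maximizes
the total over one-to-one match sets whose members are pairwise compatible:
both sides in the same order, and the arrangement pattern
(before / nested / crossing) of every two matched substructures equal on
both sides. Three provably optimal backends:

- `exact_dp` — ordered-forest interval DP; nested (crossing-free) diagrams
  only.
- `branch_and_bound` — DFS in query order pruned with a crossing-relaxed
  DP upper bound; any diagram.
- `milp` — 0/1 integer program (one variable per positive-score candidate,
  one `x_a + x_b ≤ 1` row per incompatible pair) solved by HiGHS through
  scipy; any diagram.

`auto` uses `exact_dp` when both diagrams are nested, else
`branch_and_bound`. The backends are tested to agree with each other and
with brute-force enumeration.

## Stage 2: final alignment

Full-length affine-gap NWDP over the raw sequences. Cell `(i, j)` scores
`Rs(q_i, t_j)` — or `F(i, t_j)` with a usable profile — plus a flat
**+5** for every pair anchored by stage 1 (large enough to pin the
alignment through the matched helices, small enough that sequence signal
decides between templates anchoring equally well). Templates rank by score,
ties by coverage then id, so rankings are fully deterministic.

## Libraries, metrics, chains

Libraries are directories of plain-text records (FASTA + BPSEQ + optional
PDB backbone + JSON sidecar) plus a TSV manifest; malformed records are
skipped with a warning. Chains of a multi-chain entry are concatenated with
`&` when their inter-chain base pairs strictly exceed 20% of either chain's
length (both orders are emitted); a third chain — the partner with the most
shared pairs, ties by id — may join, capped at three chains.

Coverage is aligned length over query length. Aligned-region RMSD takes the
12 backbone heavy atoms (P, OP1, OP2, O5′, C5′, C4′, C3′, O3′, C2′, C1′,
O4′, O2′) of each aligned residue pair, intersects atom names (dropping and
counting singletons), optimally superposes the two point clouds
(`scipy.spatial.transform.Rotation.align_vectors`, i.e. a Kabsch fit;
RMSD = RSSD/√n), and requires at least 3 matched atoms.

## Numerical choices

- −∞ is the finite sentinel −1e9: large enough that no admissible path can
  recover, finite so arithmetic stays IEEE-clean.
- The DP matrices are float64 numpy arrays; cell scores for the final
  alignment are built as one matrix product (`F @ dist^T` or
  `q_dist @ Rs @ dist^T`), so profile and matrix paths share one code path.
- Traceback uses explicit int8 pointer tables (no recomputation), and ties
  are broken in a fixed order (match > query-gap > template-gap), making
  alignments — not just scores — deterministic.
- All fixture randomness flows through `numpy.random.default_rng` seeded
  with `[seed, *stream]`, so every artifact is a pure function of the seed.

## Synthetic fixtures: what they emulate, what they don't

The generators produce nested structures by recursive helix/loop insertion
(helices 3–7 bp, spacers, branching), optionally splicing in one
self-contained H-type pseudoknot block, with canonical pair sequences
(Watson–Crick-heavy, 8% wobble); homologs mutate pairs compensatorily,
point-mutate loops, and apply loop-only indels; MSAs are homolog rows in
query coordinates; backbones are ideal helical traces (32.7° twist, 2.8 Å
rise) with Gaussian noise. They emulate the *combinatorial shape* of real
RNA — stacked helices, bulges, multiloops, crossing arcs, covariation —
which is what the threading machinery consumes. They are **not**
thermodynamic folds: no energy model, no non-canonical pairs, no tertiary
contacts, at most one pseudoknot, and backbone geometry that is only
loosely A-form. Conclusions about absolute accuracy on real RNAs cannot be
drawn from fixture benchmarks.

## Limitations

- Structure in, structure out: the package aligns *given* secondary
  structures; it does not predict them.
- The matcher is exact but worst-case exponential (branch and bound) or
  NP-hard-in-general (MILP) on heavily pseudoknotted diagrams; nested
  diagrams are polynomial.
- Base triples and overlapping pair annotations are rejected rather than
  modeled.
- The profile treats columns independently (no pair covariation term in the
  profile itself; covariation enters only through `Rp` on base pairs).
- RMSD evaluation requires residue-numbered backbone coordinates matching
  the alignment indexing; no sequence-based re-registration is attempted.
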