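# Methods

This note documents the model as implemented: its assumptions, the parameters
that matter, the numerical and design choices made where the design was
genuinely open, what the synthetic data does and does not emulate, and the
known limitations.

## The memory model

**Store.** A hypernetwork over `d` categorical attributes holds hyperedges in
per-anchor layers. A hyperedge is identified by the triple *(anchor,
attribute set, values)*: two edges with identical content at different
anchors are distinct objects, because the judgment machinery selects one edge
per anchor. Attribute tuples are kept sorted (canonical form), with values
aligned, so structurally equal edges hash equally regardless of how they were
sampled.

**Sampling.** `fixed` mode takes the contiguous window of `k` attributes from
each anchor (mod `d` on a ring). `random_order` draws `k_t` uniformly from
`[r1, r2]` per anchor *on every sampling call* — encoding passes and probe
observations alike — which is precisely what makes repeated encodings enrich
a random-order memory and repeated observations vary their verdicts.
`random_combination` keeps the anchor attribute and draws the remaining
`k_t − 1` attributes uniformly without replacement from all others. Line
topology never wraps; its anchoring for the random modes is a package
convention (orders clamped to the remaining width for `random_order`, one
anchor per attribute for `random_combination`) chosen so that every attribute
is always covered by its own anchor's edge — a property the completion
construction relies on.

**Weights.** The link weight is `φ(l) = 2/(1+e^(−l/C)) − 1 = tanh(l/2C)`: the
unique affine rescaling of the logistic that is zero at zero evidence, has
supremum exactly 1, is strictly increasing, and slows with larger `C`. `C`
defaults to 10 and is configurable; at `C = 10` a single co-occurrence weighs
≈ 0.05, ten weigh ≈ 0.46, and saturation is effectively reached near a few
hundred. Weights are *derived* state: only counts are stored, and a snapshot
reloaded under a different `C` rescales consistently.

Numerically, `φ` saturates to exactly 1.0 in double precision once `l/C`
exceeds ≈ 38. Analyses that need the ordering in the saturated tail (e.g.
verifying strict monotonicity out to `l = 2^20`) use
`log_link_weight_complement`, which evaluates `log(1 − φ)` in log-space and
stays exact over the entire float range.

**Judgment.** A complete probe is sampled like an encoding pass; each probe
edge activates the memory edges at its anchor with ≥ 1 matched and 0
mismatched values over the attributes both edges carry (`N_m`, the match
threshold, defaults to 0 — the only value the completion rule implies).
Verdict *old* requires a route: one activated edge per anchor, linked at
every adjacent anchor pair (wrap included on a ring), with mutually
consistent values. Route consistency is seeded with the probe's observed
values; this is provably equivalent to the pairwise-mutual rule because every
attribute's own anchor edge is activation-forced to match the probe there.
Judgment and completion never mutate the store.

**Similarity.** `S` is the maximum over closed routes of the summed link
weights, without normalisation by route length (so topologies of different
route lengths are not directly comparable on `S` — relevant when reading ROC
curves across configurations). When no route closes, `S` is the best
activated-link sum over per-anchor selections with inactivated adjacencies
contributing zero, computed by a dynamic program over the anchor sequence
(wrap adjacency included by pinning each candidate at the smallest layer).
`S = 0` when nothing activates.

**Partial probes.** A probe edge whose values are all missing carries no
evidence and cannot activate anything; such anchors are skipped by the route
search, and links are required between every surviving pair of cyclically
adjacent anchors. An anchor with observed values but no activated edge aborts
the search — its evidence contradicts memory. Each route induces a
completion (observed values plus the selected edges' values); only
completions that bind every attribute count, so completeness is *not* implied
by route existence when the mask breaks the ring into arcs. A corollary: a
completion obtained through broken arcs is not guaranteed to be judged old if
re-submitted as a complete probe, because no evidence constrained the silent
anchors; completions under masks that keep every anchor alive do carry that
guarantee, and the tests assert it in that form.

**Repeated observation** applies to verdicts only: a probe is re-judged up to
`count` times (re-sampling under random modes) and is old only if every
observation says old, stopping at the first "new". Majority voting was
rejected because it could flip a truly-encoded probe to new, which the
no-decay store makes impossible for unanimity. Completion is unaffected by
observation count: re-observing cannot change the store or the route set, so
the harness computes completion metrics from a single pass regardless of the
observation setting.

## Exactness and performance

Three internal accelerations are used; each is an exact equivalence, not an
approximation, and each is verified against the naive path in the tests:

- **Activation indexing.** While every stored edge is a contiguous window,
  candidates for a contiguous probe edge come from a single hash lookup (the
  first-two-window-values bucket, or the first-observed-position list for
  partial edges); networks containing non-contiguous edges fall back to the
  union-of-pairs index. Both paths then apply the full activation rule.
- **Plan-based route search.** Backtracking scans only the smallest candidate
  layer per contiguous arc and grows chains along stored link successor /
  predecessor lists, so link constraints are implicit in candidate
  generation. Enumeration is capped (default 10,000 routes) with a warning;
  similarity and completions are then computed over the enumerated subset.
- **Enumeration-free harness paths.** For complete probes, probe-consistent
  candidates are automatically mutually consistent, so the exact maximum
  route similarity is a layered dynamic program (`_judge_scored`), immune to
  the cap. Completion experiments need only boolean flags, computed as
  first-total-route existence checks, with the expectation check seeded by
  the full true instance (`completion_flags`).

Worst-case route search remains exponential; the cap guards pathological
networks and is configurable per call.

## Synthetic streams

The generator emulates three observed features of long-horizon phone-log
data: a cumulative old-instance ratio growing toward roughly one third,
section-wise drift of attribute distributions, and novel attribute values
appearing mid-stream. Defaults: `d = 8` attributes with alphabet sizes
(24, 30, 4, 20, 40, 2, 3, 10) — the "over 30/20/40" counts of the reference
data fixed at their floors — `n = 7000` events in 7 sections.

Mechanism and defaults:

- `repeat_prob = 0.3`: per-event probability of an exact replay of an earlier
  event, drawn with recency weighting (geometric age, `replay_decay = 0.002`,
  i.e. a ~500-event horizon; 0 means uniform history). Replays are old by
  construction; concentrated fresh draws add a few chance recurrences, which
  lands the cumulative old ratio of a 7,000-event stream near 0.33 (the
  tests assert the 0.28–0.38 band).
- `base_concentration = 0.5`: initial per-attribute Dirichlet concentration,
  giving the few-dominant-values profile of real usage logs.
- `drift_strength = 50`: each section's distribution is Dirichlet-perturbed
  from the previous one with concentration `50·p + 10⁻³`; smaller values
  drift harder, `None`/0 freezes drift (`spec.stationary()` also switches
  novelty off).
- `novelty_schedule`: per-section probability that a fresh draw carries a
  brand-new token on one attribute; the default is zero early, a bump of
  0.04/0.02 mid-stream, 0.01 late — novel values appear mid-stream, as in
  the reference data.

What the generator does **not** emulate: real logs have strong temporal
autocorrelation within sections (sessions, daily cycles), cross-attribute
dependence beyond what replay induces, and a replay-recency structure that is
unobservable from summary statistics (here it is a single geometric
parameter). Passing tests therefore show that the model's structural
guarantees and qualitative tradeoffs hold under drift, replay and novelty of
realistic magnitude — not that its absolute rates match any particular real
dataset.

## Experiment harnesses

All harnesses follow judge-then-encode (a probe never sees its own encoding;
the first section faces an empty memory), define ground truth as exact-match
recurrence, and derive independent child RNG streams per purpose (encoding,
probe sampling, masking, judgment) from their seed, so runs are
bit-reproducible and settings that share a sub-seed share the draws for the
parts they have in common. In the study-duration harness this makes the
repeated-observation setting consume the baseline's draw as its first
observation — false alarms are corrected pointwise, never added — and leaves
the store and completion metrics bit-identical across observation settings.

ROC curves are threshold sweeps over the similarity scores
(scikit-learn's implementation behind the package's `roc_curve` surface),
with trapezoidal AUC; the similarity is used for ROC even when it disagrees
with the activation verdict's implied threshold. Sections with degenerate
labels report AUC = NaN. The configuration sweep's default 13-category grid
(fixed k ∈ 2..7, random orders (2,3)…(2,6), random combinations (2,4), (2,6),
(2,7) at d = 8) is an explicit reconstruction — the original category list is
not published — and is overridable.

The online/offline comparison maintains one online store and snapshots it at
every interval boundary as the frozen offline model, so both variants see
identical masks and probe draws; the offline first interval is judged against
an empty store, which its cumulative trajectory retains.

Problem sizes used by the shipped acceptance checks — 50×4 configurations at
n = 500 for exact recall, 10 seeds × k ∈ 2..6 at n = 2000 for the tradeoff,
n = 7000 for the sectioned and online/offline experiments — are desk-scale
choices that keep the full suite in a few minutes while leaving every
qualitative comparison well out of noise.

## Limitations

- Categorical, low-dimensional data only; no numeric attributes, no distance
  between tokens. Ring/line adjacency makes distant attribute pairs interact
  only through chains of links.
- No forgetting or decay, by design: the no-miss guarantee is exact, and
  false alarms are the only error mode — recognition is strictly better than
  human performance in that respect.
- No recollection (cross-domain association); familiarity only.
- `S` grows with route length and memory age; comparisons are meaningful
  within a configuration, not across topologies.
- Route enumeration is exponential in the worst case; the cap bounds work at
  the cost of completeness of the enumerated route list (flagged by a
  warning).
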