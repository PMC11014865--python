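# Methods

## The sorting model

A single-gene tree is an unrooted leaf-labelled topology (polytomies
preserved) whose internal edges carry ultrafast-bootstrap supports on the
0–100 scale. Each edge induces a bipartition of the leaf set; bipartitions
are the unit of all decisions because they are invariant under the
arbitrary rooting a tree-inference program happens to write.

For a seed protein, a category call asks: is the seed sister to, or nested
within, a clade consisting exclusively of that category's taxa, of at
least two members? Operationally both cases are one rule — among all
non-trivial bipartitions, the seed-containing side must, after discarding
the seed itself and any seed-lineage (kareniacean) leaves, (i) contain
only leaves of the category's member group, (ii) contain at least
`min_members` (default 2) of them, and (iii) contain a witness-group leaf
where the category requires one. The call's score is the support of the
best qualifying edge; ties between equally supported edges within one
category break toward the smaller side, then lexicographically, so output
is deterministic.

Three modelling choices deserve explanation:

- **Neutral seed-lineage leaves.** Kareniacean leaves are the queries'
  own relatives; a haptophyte clade that contains a few kareniacean
  sequences still represents an endosymbiont signal. Purity checks
  therefore ignore them (configurable via `seed_lineage_neutral`), which
  is also what makes the "clade also recovers Kareniaceae as
  monophyletic" tallies computable at all.
- **Witness groups.** Every dinoflagellate is an alveolate, so without an
  extra condition every pure host-signal clade would equally qualify for
  the wider pan-alveolate category and the nested-tie rule would erase
  the host-signal class. The alveolate category therefore requires at
  least one ciliate (non-dinoflagellate alveolate) witness on the
  qualifying side.
- **Tie resolution order.** The higher score always wins first. At equal
  best scores, if the tied categories' member groups form an ancestor
  chain and their qualifying sides are correspondingly nested, the widest
  category is selected; any other equal-score tie is unresolved. This
  ordering keeps host-signal and pan-alveolate calls distinct while still
  honouring the equal-score-unresolved rule for unrelated categories.

The 75-support threshold annotates calls (`passed_threshold`) but never
suppresses them: it is an interpretation convention, not a computation
rule.

**Side-specific supports.** A genuinely unrooted document (trifurcating
root) labels each split once. A rooted binary document labels its root
split twice — once per root-adjacent clade — and those labels can differ.
The package keeps both: the canonical support of the split is their
maximum (used when comparing bipartition sets across rootings, with a
logged notice when the labels disagree), while the sorter scores a
qualifying side by the label attached to that side's own subtree, which
is the natural reading of "the branch dividing this clade from the rest".
On real tree-inference output the two conventions coincide.

**Topology tallies.** A tree supports the internal genus topology XY|Z
when some bipartition side contains every leaf of genera X and Y present
in the tree, no leaf of Z, and no non-kareniacean leaf (the strictest
purity reading; relaxing it is a matter of passing a different genus
list). The best-supported topology wins; exact ties, missing genera, or
edge-free trees are ambiguous. Kareniacean monophyly means some side
equals exactly the set of kareniacean leaves.

## Homology and alignment gates

The hit filter consumes 12-column tabular output (BLAST outfmt-6 dialect,
as produced by LAST's converter). One e-value convention is used
throughout: e ≤ 1e-10 is kept, "1e-10 or lower" drops a query in the
decontamination rule. Best-hit ordering is e-value, then bitscore, then
subject id, so results are independent of input order. "Best hit per
organism" is implemented per dataset — one per reference dataset, five
per fucoxanthin dinoflagellate library to capture recent paralogs.

The alignment filter consumes already-trimmed alignments. Gap fraction is
gap characters over total alignment columns, removal is strictly greater
than 0.75, and acceptance requires ≥ 100 columns and ≥ 10 rows after row
removal. Retained residues are never modified.

## Targeting prediction

The matrix is a position × amino-acid table of base-2 log-odds over a
contiguous window anchored on the signal-peptide cleavage site: position
−1 is the last signal-peptide residue, position 0 the first residue of
the mature peptide. The packaged geometry is −5…+21 (27 columns),
spanning the signal-peptide motif region and the arginine-rich
transit-peptide start with its conserved downstream proline; geometry is
matrix metadata, so any published matrix width loads unchanged from TSV.

`build_pssm` computes `log2(((count + τ·bg) / (N + τ)) / bg)` with
pseudocount τ = 1 by default and a uniform 0.05 background unless one is
given. Closed forms: a background-equal column scores 0; a pure column
scores `log2(1/bg)` at τ = 0.

Classification scans offsets −2…+2 around the predicted cleavage site.
Window positions outside the sequence contribute 0 (the background
expectation) so C-terminally short proteins stay classifiable; a window
entirely outside the sequence is an error. High confidence requires the
at-site score to be the maximum over offsets *and* to reach `t_high`;
`t_low` alone gives a low-confidence call. The thresholds default to 0.5
and 0.25 of the matrix's consensus (sum of per-position maxima) score —
expressing them relative to the matrix keeps the defaults meaningful for
matrices of any width or sharpness — and both are plain configuration for
calibrated use.

Variant pooling submits the original sequence and its
first-methionine-trimmed variant (accommodating translated UTRs and
spliced leaders) and prioritizes a positive signal-peptide call from
either; when both are positive the original-coordinates call is kept, and
trimmed-variant cleavage positions are shifted back into original
coordinates. The alternative route never re-implements PrediSI or
ChloroP: their tabular outputs are parsed, a protein is alt-positive only
when both agree, and rescued proteins carry the `SPTP-` prefix.

## Synthetic data and what it does (not) show

Planted gene trees attach the seed sister to a pure clade of the target
category with the planted support on the subtending edge. Background
leaves come only from groups unrelated to the planted category (no shared
ancestry with its member group, no seed-lineage leaves) and are coloured
in leaf order so that no two adjacent background leaves share a top-level
group — hence no competing category can qualify anywhere, at any support,
and recovery is exact by construction rather than probabilistic. Random
mixed trees (no planted structure) exercise the sorter against a
brute-force oracle, including the doubly-labelled root split of rooted
binary documents. Simulated alignments place an exact number of gaps per
row; simulated presequences sample cleavage-window residues from a
matrix's implied positional distributions and emit a matching SignalP
5.0-style table.

These generators validate the decision logic, not the biology: they do
not model sequence evolution, alignment error, phylogenetic
reconstruction artifacts, or realistic e-value distributions. Passing
tests show the sorting and scoring rules are implemented exactly as
specified; they say nothing about how often real gene trees are resolved
or how discriminative a real training matrix is.

## Numerical and interface choices

- Supports written as proportions (every value ≤ 1 in a tree) are scaled
  ×100; values outside [0, 100] after scaling are errors, not clamped.
  The heuristic mis-scales the pathological percent-scale tree whose
  supports are all ≤ 1.
- Missing internal supports are imputed as 0 and flagged, so they never
  qualify above any positive threshold.
- Leaf-to-dataset mapping is by ordered regex rules (first match wins),
  tolerating arbitrary suffixes on the `<dataset>_<serial>` convention;
  group membership is transitively closed over the acyclic parent map.
- Problem sizes in the acceptance script (1,000 oracle trees of ≤ 12
  leaves, 500 planted replicates per category, 1,000 scoring-invariant
  sequences, 200 presequences and motif sets) are the desk-scale sizes at
  which the exactness claims are meaningful and each check completes in
  seconds.
- Matrix TSVs carry the window coordinates in the first column, the 20
  canonical residues in the header, and the background as a trailing
  comment row. Ambiguous residues (X) score 0 in windows and are rejected
  in training data.

## Known limitations

- The sorter assumes one designated seed per tree; trees with several
  same-library paralogs need one call per chosen seed.
- Replicating published whole-proteome tallies requires the deposited
  tree archives, taxon annotations, and external predictor runs; the
  package ships the machinery and its desk-scale validation, not those
  datasets.
- Categories whose member groups partially overlap without nesting are
  resolved as unresolved on ties; no ranking between them is attempted.
- The bundled default taxon scheme is deliberately small (a realistic
  backbone of ~28 datasets); real analyses should load a scheme matching
  their reference database.
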