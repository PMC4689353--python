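# Methods

This note records the models and procedures `innlint` implements, the
parameter choices that matter, and what the synthetic test corpora do
and do not show about real nomenclature data.

## Corpus model

A record holds the raw published name, a normalized form (lowercased,
surrounding whitespace stripped) and the publication year. A name is
**multi-word** iff it contains whitespace or any non-alphanumeric
character; digits count as alphanumeric, so a trailing isotope code
like `131I` makes a name multi-word through its separating space, not
through the digits. Single-word names feed the (di)graph, length, stem
and similarity analyses; multi-word names feed the isolated-element
check only.

Duplicate normalized names are collapsed on ingestion, keeping the
first occurrence (the earliest publication when rows are in list
order) and logging a warning. Real recommended lists occasionally
re-publish or amend names; how such cases were reconciled in published
datasets is not documented, so first-wins is this package's own rule.

Random subsampling draws `round(fraction × n)` records uniformly
without replacement from a seeded generator; the same seed always
yields the same member set.

## Prohibited (di)graph scan

The prohibited patterns are `ph, th, ae, oe` (digraphs) and `y, h, k`
(single graphs). The scan is left-to-right and greedy: at each offset
digraphs are tried before single graphs, and the cursor advances past
a match, so hits never overlap and an `h` consumed by `ph`/`th` is not
double-counted, while the `h` of `ch` is counted. No prohibited
digraph contains `y`, and `ae`/`oe` cannot overlap `ph`/`th`, so no
further tie-breaks are needed. This precedence reproduces the
conventional accounting of names like *phthalylsulfathiazole*
(`ph`, `th`, `th` — plus the `y` of "phthalyl", which is itself a
prohibited graph and is reported like any other hit).

When a stem lexicon is supplied, a hit whose span lies entirely inside
a matched stem occurrence is marked **exempt** (the `k` of `-kacin` in
amikacin) but still returned. Whether published (di)graph totals
excluded stem-exempt hits is not documented, so reports carry both the
raw and the exempt-excluded totals.

Decade tables bucket by `floor(year/10)·10`; records without a year
are excluded with a warning.

## Word-length statistics

Statistics are over character counts of normalized single-word names.
The SD is the population SD by default (`sample_sd=True` switches to
the n−1 convention; published summary figures cannot be attributed to
either convention without the underlying data). Quartiles use linear
interpolation (numpy default). The mode breaks ties toward the
smallest length, for determinism. Outliers are names strictly longer
than the threshold, default 20 characters. Note that the canonical
list of nine very long 1950s-era names includes one name of exactly 20
characters; listing all nine therefore requires threshold 19, while
the default threshold yields the eight names strictly longer than 20.

## Stem lexicon and matcher

A stem entry has one or more spellings (allomorphs such as
`-profen`/`-profene`, `-metasone`/`-methasone` map to one stem id,
since spelling variation does not change meaning), an affix class per
spelling (`prefix`, `suffix`, `infix`, `freefix`), an optional parent
(hyperonym) link, a pharmacological definition, and optional
position-dependent senses (`fos` as a suffix denotes phosphorus-based
pesticides; as a prefix or infix it is the catch-all sub-sense; `grel`
and `vir` mean the same thing in any position).

Matching respects affix constraints: a suffix spelling must end the
name, a prefix must start it, an infix must be strictly interior, a
freefix may sit anywhere. Every direct match also reports its full
hyperonym chain; ancestors without a literal occurrence are flagged
`implied` — the link is taxonomic, not string containment, which is
what handles `-viroc` → `vir` in *maraviroc*. Matches overlapping a
match from a different taxon are flagged `ambiguous` and all are
reported (the ambiguity itself is the finding; the matcher does not
adjudicate). Results are ordered deepest-first, then by longer
spelling, then stem id.

For **stem-sharing** between two names, however, a preferred reading
is used: a match strictly contained in a match from a different taxon
is shadowed. *giractide*'s terminal `-tide` is shadowed by `-actide`,
and *riodipine*'s `-pine` by `-dipine` — the longer reading is the
name's actual stem and the shorter one the documented mistaken
interpretation. Without this rule, every `-actide` name would
spuriously "share" `-tide` with unrelated peptide names.

The loader validates parent links (cycles, unknown ids, duplicates are
load errors) and lints the taxonomy: unrelated stems whose spellings
differ by a single edit (`-fenin`/`-fenine`, `-micin`/`-mycin`) and
suffix sub-stems that do not terminally extend their hyperonym
(`-viroc` vs `vir`) produce warnings, not rejections — the real
Stembook contains both situations.

The shipped lexicon (`data/stems.tsv`, ~35 taxa/stems) encodes the
`-ast`, `vir` and `-mab` taxa and the individually documented stems
this package's analyses discuss. Two deliberate choices: the
single-vowel `-mab` source infixes (`-a-`, `-e-`, `-i-`, `-o-`,
`-u-`) are excluded from the general matcher because a one-vowel infix
matches virtually every name interior and would make sharing flags
vacuous (the antibody grammar handles them positionally, where they
are meaningful); and the tumour target infix `-tu-` is included even
though some printed reference tables omit it, because established
names such as *trastuzumab* require it.

Compliance: a name is `compliant` when its expected stem matches
directly, `noncompliant` when it does not, `unlisted` when no
expectation is recorded; the headline rate is the fraction
noncompliant-or-unlisted.

## Antibody grammar

`name = prefix · target · source · "mab"`, parsed right-to-left with
longest match at each stage: strip `mab`; take the longest source
infix ending at the strip point (`xizu` beats `zu`); take the longest
target infix ending where the source begins, trying the vowel-bearing
form (`toxa`) before the bare form (`tox`) — by convention the
optional vowel is dropped before a vowel-initial source; at least one
letter must remain as the prefix. Failures are values naming the
failed stage (`pre-convention` for names coined before the grammar,
e.g. *muromonab*; `no-mab`; `no-source`; `no-target`;
`empty-prefix`), never exceptions. The parser does not backtrack:
greedy longest match can shadow a rarer segmentation (assembling
target `tox` with source `i` yields `…toximab`, which re-parses with
source `xi` and then fails), and single-letter infixes make some names
genuinely ambiguous; successful parses carry the alternative
segmentations rather than a unique adjudication. Euphonic consonants
in a few real names (*catumaxomab*) also defeat the strict grammar and
surface as structured failures.

## Similarity screen

Levenshtein edit distance is the classic unit-cost dynamic program
(insertions, deletions, substitutions; no transposition — the
published worked examples are consistent with plain LED). The
screening loop uses a capped variant (length pre-check and row-minimum
early exit) that is behaviourally identical within the cap. Pairs are
unordered, deduplicated and stored canonically; self-pairs are
excluded. The screen reports both the raw sample×universe comparison
product (the convention used in published counts) and the
self-excluded count. Summaries give, per LED value 1..max, the pair
frequency and the percentages sharing a stem / sharing both a stem and
a sub-stem (one decimal place in reports; empty bins render an em
dash). Sharing is by taxonomy node identity, so allomorph pairs
(*indoprofen*/*diprofene*) share their stem.

## Synthetic generator

The generator emulates the statistical skeleton of the real
nomenclature, with ground truth recorded for every name:

* **Lengths**: rounded normal, default mean 10.5 / SD 1.7 characters,
  clipped to [4, 25]; a stem-carrying name's length is raised to the
  minimum that can host the stem (spelling length + 1, or + 2 for an
  interior infix).
* **Filler**: alternating consonant/vowel syllables over a 20-letter
  alphabet excluding `h, k, y, w` (so prohibited patterns appear only
  where injected or inside an embedded stem) and also `j, q`
  (vanishingly rare in this nomenclature; dropping them gives a round
  20-letter alphabet of 15 consonants and 5 vowels).
* **Stems**: assigned by a prevalence map; compliant names embed a
  spelling at a position legal for its affix class; a configurable
  noncompliance fraction of assigned names is generated *without* the
  stem. Every name is validated against the analysis modules: the
  scan must find exactly the injected hits plus the stem's own
  letters, the matcher must find the assigned stem iff compliant, and
  no other prevalence-map stem may occur by accident; violations
  trigger a resample (bounded at 100 retries, then a generation
  error naming the stem).
* **Decades**: drawn from a weight map (default uniform over
  1950–2009); (di)graph injection probabilities may vary by decade.
* **Near-miss pairs**: `k` random single-character edits applied to a
  randomly chosen base name, avoiding collisions and degenerate
  (distance-0) variants; the true LED is recomputed and may be below
  `k`.

Determinism: one seeded generator drives everything; identical spec
and seed give byte-identical corpus files.

What the generator does **not** emulate: real letter n-gram
statistics, pronunciation, semantic plausibility of stem/prefix
combinations, multi-word names, or the historical coupling between
decade, length and digraph use (those are injected independently). A
passing recovery test therefore shows the analysis modules are
correct and unbiased under known structure — not that real corpora
satisfy any particular value.

## Test and acceptance problem sizes

The oracle and recovery suites run at sizes chosen to give tight
checks in seconds: exhaustive memo-free recursive-oracle equivalence
for LED on all pairs of strings of length ≤ 4 over a 3-letter alphabet
(66,430 pairs), an edlib cross-check on all pairs of 300 random
strings of length ≤ 6, metric axioms on 10,000 random triples,
scanner-oracle equivalence on 10,000 random strings, matcher-oracle
equivalence on 4,000 random names against the shipped lexicon,
parameter recovery at n = 5,000 within 95% binomial/normal confidence
intervals (the length reference is the exact rounded-clipped mixture
distribution, computed at run time), planted-pair recall at 100 pairs,
and the stem-sharing gradient on a 1,200-name corpus with five planted
stem families at prevalence 0.1 each and shorter names (mean 7.5) so
that unrelated names enter the screen at LED 3–4 while family members
sit at LED 1–2 — the mechanism that produces the observed monotone
decline of stem sharing with edit distance.

## Known limitations

* Orthographic only: no phonetic similarity (Soundex/ALINE), no
  Tall-Man lettering analysis, no translated scripts.
* The shipped lexicon is a documented fragment, not the full WHO
  Stembook; full-corpus figures require the external WHO name list,
  which is public but not packaged.
* The compliance verdict trusts the expected-stem mapping it is given;
  when several stems match, verdicts expose all matches rather than
  adjudicating which is "the" stem.
* The antibody grammar targets the classic three-slot convention;
  later nomenclature revisions (suffix retirement, new class infixes)
  are out of scope.
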