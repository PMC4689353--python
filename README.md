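# innlint

Orthographic and stem-taxonomy screening of generic drug names for
look-alike confusion risk.

Confusion between look-alike medication names (mercaptopurine vs
mercaptamine, hydromorphone vs morphine) is a major source of
medication errors. The WHO designates International Nonproprietary
Names (INNs) under naming principles that pull in opposite directions:
names should be *distinctive* in spelling, yet pharmacologically
related substances should *share a common stem* (``-ast`` for
antiasthmatics, ``vir`` for antivirals, ``-mab`` for monoclonal
antibodies). Shared stems make related names orthographically close —
the taxonomy that conveys meaning is itself a driver of confusion
risk. `innlint` packages the analyses needed to quantify this tension
on any name corpus:

* **Corpus handling** — ingest delimited name lists, normalize,
  partition into single-word vs multi-word names (a name is multi-word
  iff it contains whitespace or a non-alphanumeric character), and
  draw reproducible random subsamples.
* **Orthographic compliance** — isolated letters/numbers/hyphens in
  multi-word names; the prohibited graphs and digraphs *ph, th, ae,
  oe, y, h, k* (scanned left-to-right, digraphs before single letters,
  non-overlapping; hits inside a recommended stem such as the *k* of
  ``-kacin`` in amikacin are marked exempt); character-count statistics
  with per-decade trends and a long-name outlier list.
* **Stem taxonomy** — a WHO Stembook-style lexicon of stems and
  sub-stems (hyperonyms/hyponyms) with affix classes (prefix, suffix,
  infix, "freefix"), allomorph spellings, and position-dependent
  senses; a matcher that honours affix constraints and reports implied
  hyperonyms by taxonomy link (``-viroc`` implies ``vir`` even though
  *maraviroc* does not end in "vir"); a linter that flags confusable
  stems (``-fenin``/``-fenine``, ``-micin``/``-mycin``); compliance
  verdicts against expected stems.
* **Monoclonal-antibody grammar** — parse ``-mab`` names into
  prefix + target infix + source infix + ``mab`` by longest match
  (*tras-tu-zu-mab*: tumour target, humanised source), with structured
  failures and explicit ambiguity lists.
* **Similarity screening** — Levenshtein edit distance (LED: unit-cost
  insertions, deletions, substitutions; LED(book, back) = 2), pairwise
  screening of a sample against a corpus at LED 1–4, and per-LED
  summaries of the percentage of pairs sharing a stem or sub-stem.
* **Synthetic corpora** — a generator that emulates the real
  nomenclature's structure (length distribution mean 10.5 / SD 1.7,
  configurable stem prevalence and noncompliance, (di)graph injection,
  planted near-miss pairs) with full ground truth, so every stage is
  testable without the WHO database, which is public but not
  redistributable in bulk.

## Worked example

```python
>>> import innlint as il
>>> lex = il.load_default_lexicon()

>>> il.levenshtein("mercaptopurine", "mercaptamine")
4

>>> [(m.stem_id, m.position, m.specificity) for m in il.match_stems("montelukast", lex)]
[('lukast', 'suffix', 1), ('ast', 'suffix', 0)]

>>> [(h.pattern, h.start, h.exempt) for h in il.scan_prohibited("amikacin", lex)]
[('k', 3, True)]

>>> p = il.parse_mab("trastuzumab")
>>> p.prefix, p.target, p.source, p.target_meaning, p.source_meaning
('tras', 'tu', 'zu', 'tumour', 'humanised')
```

The LED of 4 (mercaptopurine → mercaptamine: two substitutions, two
deletions) is the distance that put this pair on a real incident
report. *montelukast* is recognized as an antiasthmatic (stem
``-ast``) and, more specifically, a leukotriene receptor antagonist
(sub-stem ``-lukast``). *amikacin*'s prohibited ``k`` is excused
because it sits inside the recommended stem ``-kacin``.

The same operations are scriptable from the shell:

```sh
$ innlint decompose trastuzumab      # JSON MabParse
$ innlint match montelukast          # JSON stem matches
$ innlint generate --spec spec.yaml --out corpus.csv --truth truth.json
$ innlint run-all --corpus corpus.csv --out report/ --seed 1 --sample-frac 0.01
```

`run-all` writes the full report bundle: isolated-element flags for
multi-word names, the prohibited-(di)graph table with per-decade
counts, length statistics with outliers, stem matches and a
compliance rate on a random subsample, the LED-screened pair list with
its stem-sharing summary, and a manifest with the seed and stage
counts. Identical config and seed reproduce a byte-identical bundle.

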