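# Methods

## Coordinate model

All positions are 1-based and inclusive on both ends. An annotation
`(start, end)` covers `end − start + 1` residues/bases; two annotations
*overlap* iff they share at least one position (`a.start ≤ b.end and
b.start ≤ a.end`). Intervals `(1,5)` and `(6,9)` abut visually but do not
overlap, so they neither merge nor trigger the expand indicator. The
renderer converts to pixel space only at the edge: position *p* of a
length-*L* sequence maps to the half-open pixel band
`[label_width + (p−1)·plot_width/L, label_width + p·plot_width/L)`, which
makes the x-mapping strictly increasing and gives a block `(s, e)` a width
of exactly `(e − s + 1)·plot_width/L` pixels.

## Interval algorithms

**Merging (collapsed view).** Intervals are sorted by `(start, end, input
index)` and swept once; a running block absorbs any interval whose start
lies inside it (`start ≤ current end`). The result is the minimal set of
disjoint blocks whose covered-position set equals the union of the inputs;
each block records the input indices of its members. Strict adjacency does
not merge.

**Lane packing (expanded view).** Greedy first-fit over the same sorted
order: each interval takes the lowest-numbered lane whose last-placed
interval it does not overlap. Interval graphs are perfect, so this greedy
sweep is optimal and the lane count equals the maximum overlap depth (the
clique number), computed independently by a +1/−1 sweep over interval
endpoints. Both facts are property-tested against brute-force oracles
(exhaustive minimum coloring for n ≤ 8, per-position counting). Duplicate
identical intervals are distinct records and get distinct lanes: the
expanded view must show *every* annotation. Sub-lane order is first-fit
order; ties between identical `(start, end)` pairs keep input order, which
makes layout deterministic across runs and platforms.

## Generic JSON dialect

```
{ "title": str?, "sequenceLength": int,
  "rows": [ { "label": str, "defaultColor": str?,
              "summary": {"value": num, "label": str?, "color": str?,
                          "tooltip": str?, "url": str?}?,
              "annotations": [ {"start": int, "end": int, "label": str?,
                                "score": num?, "color": str?,
                                "tooltip": str?, "url": str?} ] } ],
  "markers": [ {"position": int, "color": str?, "label": str?} ]? }
```

Required keys: `sequenceLength`, `rows`, `rows[].label`,
`rows[].annotations`, and each annotation's `start`/`end`. Scores are
unconstrained reals — normalizing them to a shade is a style concern.
Summary values must lie in [0, 1] (fraction of the summary bar). Unknown
keys warn and are ignored so documents written for richer future dialects
still load. On write, absent optionals are omitted, the empty string counts
as absent, and key order is fixed, so writing is deterministic and
`read(write(spec)) = spec` holds for every valid normalized spec
(property-tested). Malformed JSON, missing/ill-typed keys and coordinate
violations are reported as three distinct error classes; schema errors
carry a JSON path, coordinate violations are returned as data records
(`validate_viewer`) naming row/annotation index and rule id.

## Prediction-file dialects

The three vertical formats are fixed as this package's contract (vendor
column layouts drift between program versions; files that deviate need
preprocessing, not silent guessing):

* `.ss2` — optional `#` header lines and blank lines, then
  `pos aa state coil helix strand`, state ∈ {C, H, E}.
* `.pc2` — `#` header lines, then at least `pos aa register p_score`
  (register a–g); extra columns ignored.
* `.diso` — `#` header lines, then `pos aa state confidence`,
  state ∈ {`*`, `.`}.

Parsers are whitespace-tolerant, require positions to run contiguously from
1, and name the offending line in every error. Conversion is run-length
encoding over the kept states: helix (H) and strand (E) runs become
annotations with distinct colors (coil produces none); disordered runs are
`*` residues; coiled-coil runs are residues with p-score ≤ threshold
(default 0.025, the program's customary cutoff, exposed as
`--p-threshold`). Run scores aggregate by mean (ss2, diso) and by minimum
for pc2 — a low p-score is strong evidence, so a run keeps its best value.
Lowering the threshold can only remove residues, never add them
(property-tested monotonicity).

## Rendering

Layout and emission are separate passes. `layout_viewer` resolves geometry
plus style into flat elements (blocks, annotation rects, summary bars,
marker lines, labels, indicators); `render_svg` emits SVG 1.1 with an XML
declaration, explicit width/height and viewBox. Style is a `StyleRule` of
pure functions mapping each record to color, tooltip text and link target;
resolution order is style rule → record field → row `defaultColor` → config
default. A score-shading rule is provided that linearly interpolates from
black (lowest observed score) to a base color (highest). A merged block is
colored by its first member's style — the collapsed view shows presence,
not per-member detail — and its tooltip reports the member count.

Interactivity is rendered statically: tooltips become SVG `<title>`
children (shown on hover by every major viewer) and click-through URLs
become `xlink:href` hyperlink wrappers. Expansion is chosen at render time
(`--expand`/`--expand-all`) rather than by clicking; expanding a row
without overlaps is a logged no-op since its collapsed blocks already show
every annotation. No scripts, animation or zooming are embedded.

Pages stack viewers that share one sequence length (anything else is an
alignment error listing the lengths); because `label_width` and
`plot_width` are shared, equal positions have equal x in every viewer, and
a page-level marker line is drawn at the same x in each. Output contains no
timestamps or randomness: the same spec, config and style yield
byte-identical documents.

All pixel defaults (`row_height` 20 px, `row_gap` 4, `label_width` 150,
`plot_width` 600, `summary_bar_width` 80, `summary_gap` 10, `font_size` 12,
`indicator_size` 10) are this package's choices, overridable via a flat
`key: value` config file or the `RenderConfig` dataclass; flags override
config, config overrides defaults.

## Synthetic data generator

`featuretrack.simulate` produces everything the tests need with no
downloads. `gen_viewer` builds a valid random viewer whose deepest row
attains exactly `target_max_depth`: one row stacks that many intervals over
a shared anchor position (with disjoint filler elsewhere), the other rows
draw intervals from per-lane cursors so their depth cannot exceed the
target. `gen_format_file` emits dialect-conformant `.ss2`/`.pc2`/`.diso`
text from random state runs (uniform run lengths, 3–12 residues by default
over a 400-residue sequence — typical scales for secondary-structure
elements) together with the ground-truth row bookkept from the generator's
own run structure, never by calling the converter under test. All
randomness flows from one explicit seed; a fixed seed reproduces output
byte-for-byte.

These are statistical fixtures, not biophysical simulations: state runs are
independent of residue identity, scores are uniform draws, and no
correlation structure of real predictors is emulated. Passing tests
therefore demonstrate correctness of parsing, filtering, run-length
encoding, layout and rendering — not predictive validity of any upstream
program, and not robustness to vendor format drift beyond the documented
dialects.

## Numerical and design choices

* Pixel coordinates are emitted with three decimals (trailing zeros
  stripped), ample for sub-1e-6 alignment at viewer scale while keeping
  output stable.
* Interval ties break on input order everywhere; all sorts are stable.
* Degenerate inputs: empty rows render as an empty band; an empty viewer
  still shows its frame and title; empty interval lists give zero depth,
  zero tracks and no blocks.
* `.pc2` thresholds must be strictly positive; zero would keep nothing and
  almost always indicates a unit mistake.
* Problem sizes in the test and acceptance suites (500 interval sets for
  the exhaustive-coloring cross-check at n ≤ 8, 100 merge sets at n ≤ 100,
  ~100 generated prediction files, 200 round-trip documents) were chosen to
  exercise every branch while keeping the whole suite in a few seconds.

## Known limitations

* One sequence per viewer; no multiple-sequence alignment, no genome-scale
  tiling or zooming.
* Live interactivity (cross-viewer mouseover highlighting, click callbacks)
  is out of scope; the static analogues are titles and hyperlinks.
* Transmembrane/signal-peptide predictions require submitting sequences to
  a remote prediction service and are not fetched; such results can be
  supplied through the generic JSON dialect instead.
* Named CSS colors cannot be score-shaded (interpolation needs an RGB
  parse); they pass through unchanged.
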