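# featuretrack

Render annotated features of a single nucleotide or protein sequence —
domain boundaries, binding sites, secondary-structure or disorder
predictions, peptide coverage — as coordinate-aligned, publication-quality
SVG track views. The package is for bioinformaticians who have per-sequence
annotations from heterogeneous sources and want one static, dependency-free
picture that lines them all up.

## What it does

A sequence of length *L* is drawn horizontally with position 1 at the left
edge and position *L* at the right; position *p* occupies the pixel band

```
x_left(p)  = label_width + (p − 1) · plot_width / L
x_right(p) = label_width +  p      · plot_width / L
```

(1-based, inclusive coordinates throughout). Each annotation source is one
labeled row of blocks. When annotations overlap — e.g. one covering
positions 2–10 and another 8–19, which share 8–10 — the *collapsed* view
merges them into a single block 2–19 and flags the row with a small
plus-sign indicator; the *expanded* view separates them onto sub-tracks
("lanes"). Lane packing is greedy first-fit over intervals sorted by
(start, end, input order), which on interval graphs is optimal: the number
of lanes always equals the maximum overlap depth, the largest number of
annotations stacked over any one position.

Rows may carry a summary bar at the right (a horizontal bar proportional to
a value in [0, 1], e.g. sequence coverage), vertical marker lines can flag
positions of interest (e.g. trypsin cut sites) across all rows and viewers,
and several viewers of the same sequence stack on one page with identical
x-mapping so positions can be compared directly. Tooltips are emitted as
SVG `<title>` elements and click-throughs as SVG hyperlinks, so the output
is a standalone, script-free document.

Inputs:

* a generic annotation JSON dialect (see `docs/methods.md`), covering
  tooltips, URLs, scores, row colors, summaries and markers;
* `.ss2` files (psipred secondary structure, VFORMAT);
* `.pc2` files (Paircoil2 coiled-coil predictions, filtered by p-score,
  default cutoff 0.025 — lower p means stronger evidence);
* `.diso` files (DISOPRED disorder predictions).

Per-residue predictions become annotations by run-length encoding: one
annotation per maximal run of residues in an annotated state, scored by the
run's mean score (ss2, diso) or minimum p-score (pc2).

## Worked example

Convert a 4-residue psipred file and render it:

```
$ printf '1 A C 0.9 0.05 0.05\n2 K H 0.1 0.8 0.1\n3 L H 0.1 0.9 0.1\n4 V C 0.9 0.05 0.05\n' > demo.ss2
$ featuretrack convert demo.ss2 --format ss2 -o demo.json
$ featuretrack render demo.json -o demo.svg
$ featuretrack validate demo.json
valid
```

`demo.json` contains one helix annotation covering the H run at positions
2–3, scored by the mean helix score (0.8 + 0.9)/2 = 0.85:

```json
{
  "title": "demo.ss2",
  "sequenceLength": 4,
  "rows": [
    {
      "label": "secondary structure",
      "annotations": [
        {"start": 2, "end": 3, "label": "helix", "score": 0.85,
         "color": "#2ca05a", "tooltip": "helix 2–3"}
      ]
    }
  ]
}
```

and `demo.svg` is a standalone SVG 1.1 document whose green block spans
exactly the pixel band of positions 2–3.

The same operations are available as a library:

```python
from featuretrack import (Interval, merge_blocks, assign_tracks,
                          read_generic_json, render_viewer)

merge_blocks([Interval(2, 10), Interval(8, 19)])
# [MergedBlock(start=2, end=19, members=(0, 1))]
assign_tracks([Interval(2, 10), Interval(8, 19)]).n_tracks
# 2
```

Rows are expanded at render time with `--expand LABEL` (repeatable) or
`--expand-all`; `--markers 12,88` draws page-level marker lines;
`--config FILE` reads flat `key: value` display parameters (row heights,
widths, colors, font size). Exit codes: 0 success, 1 invalid document
(`validate`), 2 parse/schema error, 3 mismatched sequence lengths on one
page, 4 inapplicable parameter.

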