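# loopalign

Automated crystal-loop centering and unattended data-collection logic for
macromolecular crystallography (MX) beamlines — runnable entirely on a desk,
against a built-in virtual beamline.

High-throughput MX beamlines measure tens of cryo-cooled protein crystals per
hour without a human in the loop.  Each sample (a crystal held in a micro-loop
on a pin) must be mounted, optically centered so the loop tip sits on the
rotation axis at the X-ray beam position, diffraction-centered with raster
scans that count spots per grid position, and finally collected — or skipped
when nothing diffracts.  `loopalign` implements that whole chain:

* **virtual_beamline** — a deterministic simulator: a parametric sample
  (pin + planar elliptical loop + optional crystal), motor state (x, y, z
  translations, ω rotation, χ/φ orientation axes), two cameras (wide-field
  top camera and on-axis sample microscope), and a Poisson spot-count model
  for grid scans.  It doubles as the test-fixture generator: no hardware, no
  image downloads.
* **vision** — silhouette segmentation (Otsu), loop-tip detection, projected
  area, vertical extent and bounding box.
* **centering** — top-camera calibration, prelocation, tip centering at two
  orthogonal ω, flat-face finding by sinusoid fitting, loop-thickness
  measurement, bounding box, and raster-grid generation.
* **gridscan** — spot-count aggregation, four-mode thresholding
  (default / strong / weak / always-collect), best-box selection, the
  90°-away vertical line scan, the skip decision, and heat-map overlays.
* **orchestrator** — a resumable per-sample state machine
  (`safety_check → mount → optical_center → diff_center → daq`) with an
  append-only JSON-lines journal.
* **spreadsheet** — the per-sample CSV contract (mount address, method,
  acquisition parameters, multi-orientation χ,φ lists) with collect-all
  validation.
* **report** — a deterministic HTML report: per-step status glyphs and
  sample / heat-map thumbnails.

## The model at the core

A planar loop viewed along the beam has a projected area that is 180°-periodic
in the rotation angle ω and maximal when the loop face is parallel to the
image plane.  After the tip is centered, the sample is rotated over 180° with
images every 40° and the measured areas are fitted with

    area(ω) ≈ c₀ + c₁·cos 2ω + c₂·sin 2ω,      ω* = ½·atan2(c₂, c₁)

ω* is the flat-face angle: the raster scan is performed there, over the loop's
bounding box at one beam-size spacing (`ceil(extent / beam)` boxes per axis).
The best grid box is the one with the most diffraction spots above the
threshold for the sample's mode; a vertical line scan at ω* + 90° then
resolves the crystal position along the former viewing axis.  If every box of
either scan stays below threshold, the sample is skipped and automation moves
on.  The vertical scans span the *full* region-of-interest height rather than
the measured loop thickness, because samples can settle between optical and
diffraction centering (icy pin bases); the package includes a benchmark
demonstrating exactly why.

## Worked example

Three samples: two with crystals, one empty loop.

```python
import numpy as np
from loopalign import VirtualBeamline, random_scene
from loopalign.orchestrator import run
from loopalign.report import build_report
from loopalign.spreadsheet import read, validate

rows = validate(read("samples.csv")).raise_if_invalid()

def scenes(row_index, row, rng):          # the virtual puck
    return random_scene(rng, with_crystal=row_index != 1,
                        background_spots=0 if row_index == 1 else 2)

bl = VirtualBeamline()
records = run(rows, bl, "journal.jsonl", seed=7, out_dir="out",
              scene_source=scenes)
for rec in records:
    print(f"{rec.sample:15s} daq={rec.steps['daq'].status:8s} "
          f"decision={rec.decision}")
build_report(records, "out")
```

prints

```
lysozyme_a      daq=success  decision={'outcome': 'collect', 'best_2d_index': [3, 12], 'best_line_index': 3, 'peak_2d': 98, 'peak_line': 74}
empty_loop      daq=skipped  decision={'outcome': 'skip', 'best_2d_index': None, 'best_line_index': None, 'peak_2d': None, 'peak_line': None}
thermolysin_b   daq=success  decision={'outcome': 'collect', 'best_2d_index': [6, 10], 'best_line_index': 4, 'peak_2d': 85, 'peak_line': 95}
```

`lysozyme_a`'s crystal produced a 98-spot peak in box (3, 12) of the 2D
raster and a 74-spot peak in line box 3, so a dataset manifest was written;
the empty loop never reached the 10-spots-per-box default threshold and its
DAQ step was skipped (frog glyph in the report); the run continued to the
third sample.  `out/report.html` holds the summary table and per-sample
sheets with the heat-map overlays.

The same flow is available from the shell:

```sh
loopalign run --spreadsheet samples.csv --journal j.jsonl --out out --seed 7
loopalign resume --journal j.jsonl --spreadsheet samples.csv --out out
loopalign report --journal j.jsonl --out out
```

Exit codes: 0 done, 2 automation stopped on a failed step, 3 validation
error.  A run that stops (e.g. a mount failure) can be resumed from its
journal; completed rows are not re-executed and the failing row restarts at
its first non-successful step with identical seeded outcomes.

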