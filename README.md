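# xmerfish

Simulation and decoding of **expansion-microscopy MERFISH** measurements.

MERFISH (multiplexed error-robust FISH) identifies hundreds of RNA species in
single cells by reading a combinatorial binary barcode over sequential rounds
of single-molecule FISH imaging. Its detection efficiency collapses when the
areal density of targeted molecules is high enough that diffraction-limited
spots overlap; physically expanding the specimen in a swellable gel (here
2.3× per dimension, ~12× in volume) moves molecules apart and restores
efficiency. This package implements the computational core of that workflow
for simulation studies and method development:

- **codebook** — the 16-bit, Hamming-weight-4, minimum-Hamming-distance-4
  (MHD4) code: 140 barcodes enumerated from the weight-4 codewords of the
  extended Hamming [16,11,4] code, with single-bit error-correcting lookup.
- **probe_design** — encoding-probe assembly: randomly tiled 30-nt target
  regions (up to 20-nt overlap, 92 probes per RNA), two of four readout
  sequences per probe, adenosine spacers and cleavable priming regions
  (72-nt product, 112-nt full oligo).
- **simulate** — synthetic ground truth and 8-round × 2-channel image
  stacks: Gaussian spots (σ = 1.6 px, 109-nm pixels), lognormal brightness,
  background/shot/read noise, fiducial beads, per-round drift, per-bit
  readout errors, and a linear expansion factor applied to coordinates.
- **decode** — the pixel-based pipeline: bead registration, high-pass /
  Richardson–Lucy / low-pass filtering, iterative per-bit intensity
  equalization, 16-dimensional pixel-vector barcode assignment within the
  single-bit-error distance √(2−√3) ≈ 0.5176, 3-D assembly with
  26-connectivity, and ground-truth matching.
- **segment** — watershed segmentation of cells from inverted RNA density
  with nucleus seeds, molecule-to-cell assignment, volumes in pre-expansion
  units.
- **analyze** — the density → efficiency benchmark, Fano-factor expression
  statistics, two-condition count comparisons, and a simple smFISH spot
  caller with adjacent-z merging.

## Worked example

```python
from xmerfish.analyze import run_pipeline_once
from xmerfish.codebook import assign_labels, generate_mhd4
from xmerfish.decode import DecodeConfig
from xmerfish.simulate import FieldGeometry, OpticsModel

book = assign_labels(generate_mhd4(16),
                     [f"Gene-{i+1:03d}" for i in range(129)], 11, seed=0)
optics = OpticsModel(bead_count=0)
for factor in (1.0, 2.3):
    geom = FieldGeometry(fov_x=40.0, fov_y=40.0, expansion_factor=factor)
    res = run_pipeline_once(book, 3.5, geom, optics, DecodeConfig(), seed=5)
    print(f"expansion {factor}x: efficiency {res.efficiency:.3f}, "
          f"precision {res.precision:.3f}")
```

prints

```
expansion 1.0x: efficiency 0.487, precision 0.999
expansion 2.3x: efficiency 0.936, precision 0.999
```

At 3.5 molecules/µm² per optical section an unexpanded field decodes fewer
than half of its molecules — overlapping spots corrupt the 16-bit pixel
vectors — while the same field expanded 2.3× decodes >90% of them, because
the image-frame density drops by 2.3² ≈ 5.3-fold. Precision stays near 1:
the code detects rather than miscalls ambiguous pixels.

The `examples/` directory holds short narrative scripts, one per
capability: codebook + probes, simulate + decode, the density benchmark,
and cell segmentation + statistics. A thin CLI mirrors the main entry
points (`xmerfish codebook|probes|simulate|decode|benchmark-density`).

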