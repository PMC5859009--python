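"""Encoding-probe assembly: target tiling, readout pairing, primer layout.

Each RNA species is targeted by up to 92 encoding probes.  A probe carries a
30-nt region complementary to the transcript, flanked by two 20-nt readout
sequences drawn from the four readouts assigned to that RNA (one per on-bit
of its barcode), with a single adenosine spacer on each side of the target
region.  The full synthesized oligo adds a 20-nt 5' priming region ending in
thymine (the uracil-cleavage junction) and a 20-nt 3' priming region (reverse
complement of the T7 promoter).  Enzymatic cleavage of both priming regions
leaves a 72-nt product; the pre-cleavage oligo is 112 nt.

Neighbouring probes on a transcript may share up to 20 nt of target sequence,
which lets transcripts as short as ~1 kb carry the full 92-probe load.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Seq import Seq

__all__ = [
    "TargetTile",
    "EncodingProbe",
    "tile_targets",
    "build_probe",
    "design_gene_probes",
    "reverse_complement",
    "DEFAULT_PRIMER_5",
    "DEFAULT_PRIMER_3",
]

PROBE_LEN = 30
READOUT_LEN = 20
MAX_OVERLAP = 20
N_PROBES_DEFAULT = 92

# Placeholder 20-mer with the required terminal thymine at the cleavage
# junction; real designs supply their own primer pair via config.
DEFAULT_PRIMER_5 = "CGCAAACTGGTGCGGAAGGT"
# Reverse complement of the 20-nt T7 promoter TAATACGACTCACTATAGGG.
DEFAULT_PRIMER_3 = "CCCTATAGTGAGTCGTATTA"


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class TargetTile:
    """A 30-nt target window on a transcript, 0-based half-open."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end - self.start != PROBE_LEN:
            raise ValueError("target tiles are exactly 30 nt")


@dataclass(frozen=True)
class EncodingProbe:
    gene: str
    tile: TargetTile
    readout_a: str
    readout_b: str
    full_sequence: str
    product_sequence: str


def tile_targets(
    transcript_length: int,
    n_probes: int = N_PROBES_DEFAULT,
    probe_len: int = PROBE_LEN,
    max_overlap: int = MAX_OVERLAP,
    seed: int = 0,
) -> list[TargetTile]:
    """Select up to ``n_probes`` 30-nt tiles with pairwise overlap <= 20 nt.

    Start positions are drawn uniformly at random from all valid
    configurations (sorted starts with consecutive gaps >= probe_len -
    max_overlap) via the standard gap transform: sample offsets in the slack
    interval, sort, and add the cumulative minimum step.  When the transcript
    cannot hold ``n_probes`` tiles at the minimum spacing, the densest regular
    tiling with the maximum feasible count is returned instead; callers can
    detect the shortfall from ``len(result) < n_probes``.

    Raises
    ------
    ValueError
        If the transcript is shorter than one probe.
    """
    if transcript_length < probe_len:
        raise ValueError(
            f"transcript of {transcript_length} nt cannot hold a {probe_len}-nt probe"
        )
    if n_probes < 1:
        raise ValueError("n_probes must be >= 1")
    step = probe_len - max_overlap  # minimum start-to-start spacing
    span = transcript_length - probe_len  # last valid start
    max_feasible = span // step + 1
    n = min(n_probes, max_feasible)
    if n < n_probes:
        # densest regular tiling
        starts = np.arange(n) * step
    else:
        slack = span - (n - 1) * step
        rng = np.random.default_rng(seed)
        offsets = np.sort(rng.integers(0, slack + 1, size=n))
        starts = offsets + np.arange(n) * step
    return [TargetTile(int(s), int(s) + probe_len) for s in starts]


def build_probe(
    gene: str,
    tile: TargetTile,
    target_seq: str,
    assigned_readouts: dict[str, str],
    seed: int = 0,
    primer_5: str = DEFAULT_PRIMER_5,
    primer_3: str = DEFAULT_PRIMER_3,
) -> EncodingProbe:
    """Assemble one encoding probe.

    ``assigned_readouts`` maps the gene's four readout names to their 20-nt
    sequences; two are drawn without replacement.  The product is
    ``readout_a + A + revcomp(target) + A + readout_b`` (72 nt); the full
    oligo adds the two 20-nt priming regions (112 nt).
    """
    if len(target_seq) != tile.end - tile.start:
        raise ValueError("target_seq length must match the tile")
    if len(assigned_readouts) < 4:
        raise ValueError("each RNA carries four assigned readouts")
    rng = np.random.default_rng(seed)
    names = sorted(assigned_readouts)
    a, b = rng.choice(len(names), size=2, replace=False)
    return _assemble(gene, tile, target_seq, names[a], names[b],
                     assigned_readouts, primer_5, primer_3)


def _assemble(gene, tile, target_seq, name_a, name_b, readouts, primer_5, primer_3):
    product = (
        readouts[name_a] + "A" + reverse_complement(target_seq) + "A" + readouts[name_b]
    )
    if not primer_5.endswith("T"):
        raise ValueError("5' primer must end in T (uracil cleavage junction)")
    full = primer_5 + product + primer_3
    return EncodingProbe(
        gene=gene,
        tile=tile,
        readout_a=name_a,
        readout_b=name_b,
        full_sequence=full,
        product_sequence=product,
    )


def design_gene_probes(
    gene: str,
    transcript_seq: str,
    assigned_readouts: dict[str, str],
    n_probes: int = N_PROBES_DEFAULT,
    seed: int = 0,
    primer_5: str = DEFAULT_PRIMER_5,
    primer_3: str = DEFAULT_PRIMER_3,
) -> list[EncodingProbe]:
    """Tile a transcript and assemble its probe set.

    Readout pairs are drawn independently per probe; afterwards, if any of the
    gene's four readouts is absent from the set (possible by chance for small
    probe counts), the minimal number of probes is re-paired so that every
    readout bit is covered.
    """
    tiles = tile_targets(len(transcript_seq), n_probes=n_probes, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    names = sorted(assigned_readouts)
    probes = []
    for tile in tiles:
        a, b = rng.choice(4, size=2, replace=False)
        probes.append(
            _assemble(gene, tile, transcript_seq[tile.start:tile.end],
                      names[a], names[b], assigned_readouts, primer_5, primer_3)
        )
    # guarantee every readout appears at least once
    used = {p.readout_a for p in probes} | {p.readout_b for p in probes}
    missing = [nm for nm in names if nm not in used]
    for k, nm in enumerate(missing):
        p = probes[k]
        probes[k] = _assemble(gene, p.tile,
                              transcript_seq[p.tile.start:p.tile.end],
                              nm, p.readout_b, assigned_readouts, primer_5, primer_3)
    return probes
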