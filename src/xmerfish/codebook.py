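"""16-bit MHD4 codebook construction and error-corrected barcode lookup.

MERFISH identifies RNA species by binary barcodes read out over sequential
hybridization rounds.  The code used here is the 16-bit, constant
Hamming-weight-4, minimum Hamming-distance-4 ("MHD4") code: every barcode
carries exactly four "on" bits, and any two barcodes differ in at least four
bit positions.  Constant weight avoids bias from the asymmetric rates of
1->0 and 0->1 readout errors; distance 4 makes every single-bit error
correctable (the corrupted word has a unique valid barcode at Hamming
distance 1) and every double-bit error detectable.

The codebook is constructed by enumerating the codewords of the extended
Hamming [16,11,4] code and keeping the 140 words of weight 4, which is a
maximal 16-bit weight-4 distance-4 set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Barcode",
    "Codebook",
    "generate_mhd4",
    "assign_labels",
    "lookup_bits",
    "read_codebook_csv",
    "write_codebook_csv",
]

N_BITS = 16
WEIGHT = 4
MIN_DISTANCE = 4


@dataclass(frozen=True)
class Barcode:
    """One codeword: 16 ordered bits, its index in the codebook, and a label.

    The label is a gene name, ``Blank-<k>`` for a misidentification control,
    or ``""`` while unassigned.
    """

    bits: tuple[int, ...]
    index: int
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.bits) != N_BITS:
            raise ValueError(f"barcode must have {N_BITS} bits, got {len(self.bits)}")
        if sum(self.bits) != WEIGHT:
            raise ValueError(f"barcode must have Hamming weight {WEIGHT}")

    @property
    def bit_string(self) -> str:
        return "".join(str(b) for b in self.bits)

    @property
    def on_bits(self) -> tuple[int, ...]:
        """0-based positions of the on bits (bit 0 = round 1, channel 1)."""
        return tuple(int(i) for i in np.flatnonzero(self.bits))


@dataclass
class Codebook:
    """An ordered set of MHD4 barcodes with optional gene/blank assignments."""

    barcodes: list[Barcode]
    readout_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.readout_names:
            self.readout_names = [f"RO{i + 1:02d}" for i in range(N_BITS)]
        labels = [b.label for b in self.barcodes if b.label]
        if len(labels) != len(set(labels)):
            raise ValueError("barcode labels must be unique")

    def __len__(self) -> int:
        return len(self.barcodes)

    def __iter__(self):
        return iter(self.barcodes)

    @property
    def n_bits(self) -> int:
        return N_BITS

    @property
    def n_genes(self) -> int:
        return sum(1 for b in self.barcodes if b.label and not b.label.startswith("Blank-"))

    @property
    def n_blanks(self) -> int:
        return sum(1 for b in self.barcodes if b.label.startswith("Blank-"))

    @property
    def bit_matrix(self) -> np.ndarray:
        """(n_barcodes, 16) uint8 matrix of bit values, row order = index order."""
        return np.array([b.bits for b in self.barcodes], dtype=np.uint8)

    @property
    def labels(self) -> list[str]:
        return [b.label for b in self.barcodes]

    def is_blank(self, index: int) -> bool:
        return self.barcodes[index].label.startswith("Blank-")

    def min_pairwise_distance(self) -> int:
        m = self.bit_matrix.astype(np.int16)
        # pairwise Hamming distances via broadcasting; exhaustive by design
        d = np.abs(m[:, None, :] - m[None, :, :]).sum(axis=2)
        iu = np.triu_indices(len(m), k=1)
        return int(d[iu].min())


def _extended_hamming_generator() -> np.ndarray:
    """Generator matrix (11 x 16) of the extended Hamming [16,11,4] code.

    Built from the [15,11,3] Hamming code whose parity-check columns are the
    binary representations of 1..15, with parity bits at positions 1, 2, 4, 8
    (1-based), then extended by an overall even-parity bit.
    """
    parity_pos = [1, 2, 4, 8]
    data_pos = [p for p in range(1, 16) if p not in parity_pos]
    gen = np.zeros((11, 16), dtype=np.uint8)
    for k, pos in enumerate(data_pos):
        word = np.zeros(15, dtype=np.uint8)
        word[pos - 1] = 1
        # parity bit p covers every position whose binary expansion contains p
        for p in parity_pos:
            word[p - 1] = 1 if pos & p else 0
        gen[k, :15] = word
        gen[k, 15] = word.sum() % 2
    return gen


def generate_mhd4(n_bits: int = 16) -> Codebook:
    """Enumerate the weight-4 codewords of the extended Hamming [16,11,4] code.

    Returns the 140-word MHD4 codebook in lexicographic bit-string order,
    unassigned (empty labels).  Deterministic: no randomness is involved.

    Parameters
    ----------
    n_bits : int
        Barcode length; only 16 is supported.

    Raises
    ------
    ValueError
        If ``n_bits`` is not 16.
    """
    if n_bits != N_BITS:
        raise ValueError(f"unsupported barcode length {n_bits}; only {N_BITS} bits supported")
    gen = _extended_hamming_generator()
    messages = ((np.arange(2**11)[:, None] >> np.arange(11)) & 1).astype(np.uint8)
    words = messages @ gen % 2
    weight4 = words[words.sum(axis=1) == WEIGHT]
    # canonical ordering: lexicographic by bit string
    order = np.lexsort(weight4.T[::-1])
    weight4 = weight4[order]
    barcodes = [
        Barcode(bits=tuple(int(v) for v in row), index=i) for i, row in enumerate(weight4)
    ]
    return Codebook(barcodes=barcodes)


def assign_labels(
    codebook: Codebook,
    gene_names: list[str],
    n_blanks: int,
    seed: int,
) -> Codebook:
    """Assign gene names and blank controls to barcodes by a seeded permutation.

    Genes and blanks are mapped onto a random permutation of the codewords;
    unassigned codewords are dropped.  The same seed always yields the same
    assignment.  Blanks are auto-named ``Blank-1..k``.
    """
    if len(set(gene_names)) != len(gene_names):
        raise ValueError("gene names must be unique")
    n_labels = len(gene_names) + n_blanks
    if n_labels > len(codebook):
        raise ValueError(
            f"cannot assign {n_labels} labels to a {len(codebook)}-word codebook"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(codebook))
    labels = list(gene_names) + [f"Blank-{k + 1}" for k in range(n_blanks)]
    chosen = sorted(perm[:n_labels])
    label_for = dict(zip(perm[:n_labels], labels))
    barcodes = [
        Barcode(bits=codebook.barcodes[i].bits, index=new_i, label=label_for[i])
        for new_i, i in enumerate(chosen)
    ]
    return Codebook(barcodes=barcodes, readout_names=list(codebook.readout_names))


def lookup_bits(
    raw_bits, codebook: Codebook
) -> tuple[int | None, int]:
    """Decode a raw 16-bit word against the codebook with 1-bit correction.

    Returns ``(index, 0)`` on an exact match, ``(index, 1)`` when the word is
    at Hamming distance 1 from exactly one barcode (guaranteed unique by the
    distance-4 property), and ``(None, 0)`` otherwise.
    """
    raw = np.asarray(raw_bits, dtype=np.uint8)
    if raw.shape != (N_BITS,):
        raise ValueError(f"raw_bits must have length {N_BITS}")
    dists = np.abs(codebook.bit_matrix.astype(np.int16) - raw.astype(np.int16)).sum(axis=1)
    best = int(dists.min())
    if best == 0:
        return int(np.argmax(dists == 0)), 0
    if best == 1:
        return int(np.argmax(dists == 1)), 1
    return None, 0


def write_codebook_csv(codebook: Codebook, path) -> None:
    """Write ``name,id,barcode`` CSV; barcode as a 16-char 0/1 string in
    readout order (bit 1 = round 1 channel 1 ... bit 16 = round 8 channel 2)."""
    import pandas as pd

    df = pd.DataFrame(
        {
            "name": [b.label or f"barcode-{b.index}" for b in codebook],
            "id": [b.index for b in codebook],
            "barcode": [b.bit_string for b in codebook],
        }
    )
    df.to_csv(path, index=False)


def read_codebook_csv(path) -> Codebook:
    """Read a codebook written by :func:`write_codebook_csv`."""
    import pandas as pd

    df = pd.read_csv(path, dtype={"barcode": str})
    barcodes = [
        Barcode(
            bits=tuple(int(c) for c in row.barcode),
            index=int(row.id),
            label="" if str(row.name).startswith("barcode-") else str(row.name),
        )
        for row in df.itertuples()
    ]
    return Codebook(barcodes=barcodes)
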