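"""Build the 140-word MHD4 codebook and design encoding probes for one gene.

The 16-bit code has constant Hamming weight 4 and minimum pairwise distance
4, so any single readout error is correctable and any double error is
detectable.  Each gene gets 92 encoding probes: a 30-nt target region
flanked by two of its four readout sequences, 72 nt after primer cleavage.
"""

import numpy as np

from xmerfish.codebook import assign_labels, generate_mhd4, lookup_bits
from xmerfish.probe_design import design_gene_probes

book = generate_mhd4(16)
print(f"codebook: {len(book)} barcodes, weight {book.bit_matrix.sum(1)[0]}, "
      f"min pairwise distance {book.min_pairwise_distance()}")

book = assign_labels(book, [f"Gene-{i + 1:03d}" for i in range(129)], 11, seed=0)
print(f"assigned: {book.n_genes} genes + {book.n_blanks} blank controls")

# single-bit error correction in action
b = book.barcodes[0]
corrupted = list(b.bits)
corrupted[3] ^= 1
idx, n_corr = lookup_bits(corrupted, book)
print(f"barcode {b.label} with bit 4 flipped decodes back to "
      f"{book.barcodes[idx].label} ({n_corr} bit corrected)")

# probes for a synthetic 1.2-kb transcript
rng = np.random.default_rng(1)
transcript = "".join(rng.choice(list("ACGT"), 1200))
readouts = {book.readout_names[i]: "".join(rng.choice(list("ACT"), 20))
            for i in b.on_bits}
probes = design_gene_probes(b.label, transcript, readouts, n_probes=92, seed=2)
print(f"{len(probes)} probes; product {len(probes[0].product_sequence)} nt, "
      f"full oligo {len(probes[0].full_sequence)} nt")
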