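"""Nucleotide alphabet helpers shared across the pipeline.

miRNA mature sequences are handled on the RNA alphabet (ACGU), transcripts
(lncRNAs, mRNA 3'UTRs, decoys, reads) on the DNA alphabet. Pairing is always
between an RNA base (miRNA) and a DNA base on the transcript sense strand.
"""

from __future__ import annotations

import numpy as np

RNA_ALPHABET = frozenset("ACGU")
DNA_ALPHABET = frozenset("ACGTN")

# DNA base on the transcript sense strand that Watson-Crick pairs an RNA base.
_PAIR_DNA = {"A": "T", "U": "A", "G": "C", "C": "G"}

#: Watson-Crick (miRNA base, transcript base) pairs.
WC_PAIRS = frozenset({("A", "T"), ("U", "A"), ("G", "C"), ("C", "G")})
#: G:U wobble pairs (rG:dT and rU:dG).
WOBBLE_PAIRS = frozenset({("G", "T"), ("U", "G")})


def as_rna(seq: str) -> str:
    return seq.strip().upper().replace("T", "U")


def as_dna(seq: str) -> str:
    return seq.strip().upper().replace("U", "T")


def check_alphabet(seq: str, alphabet: frozenset, what: str) -> None:
    bad = set(seq) - alphabet
    if bad:
        raise ValueError(f"{what} contains characters outside its alphabet: {sorted(bad)}")


def wc_site(mirna_segment: str) -> str:
    """Transcript-sense DNA subsequence that pairs a miRNA segment.

    Both the input (RNA) and output (DNA) are written 5'->3'; the duplex is
    antiparallel, hence the reversal.
    """
    return "".join(_PAIR_DNA[b] for b in reversed(mirna_segment))


def random_seq(rng: np.random.Generator, length: int, alphabet: str = "ACGT") -> str:
    letters = np.frombuffer(alphabet.encode(), dtype="S1")
    return b"".join(letters[rng.integers(0, len(letters), size=length)]).decode()


def random_seqs(rng: np.random.Generator, lengths, alphabet: str = "ACGT") -> list[str]:
    return [random_seq(rng, int(n), alphabet) for n in lengths]
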