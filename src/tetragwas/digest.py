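"""In-silico reduced-representation (GBS) fragment prediction.

Double digestion with a rare cutter (PstI, NsiI or SbfI) and a frequent
cutter (MseI or BfaI) partitions each sequence at the pooled cut
positions; only fragments with one rare- and one frequent-cutter end in a
sequenceable size range (200-500 bp by default) become GBS tags, because
two-enzyme GBS chemistry amplifies only mixed-end fragments. PstI is
methylation-sensitive in vivo; this is modelled as an optional random
mask over rare-cutter sites.

All five built-in recognition sites are palindromic, so top-strand
matching is sufficient. Cut offsets follow REBASE top-strand definitions
(PstI CTGCA^G, MseI T^TAA, NsiI ATGCA^T, SbfI CCTGCA^GG, BfaI C^TAG).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

SEQUENCE_END = "end"


@dataclass(frozen=True)
class Enzyme:
    name: str
    recognition_site: str
    cut_offset: int   # bases from site start to the top-strand cut

    def __post_init__(self) -> None:
        if len(self.recognition_site) not in (4, 6, 8):
            raise ValueError("recognition site must be 4, 6 or 8 bases")
        if not 0 <= self.cut_offset <= len(self.recognition_site):
            raise ValueError("cut offset outside the recognition site")
        if any(c not in _IUPAC for c in self.recognition_site):
            raise ValueError("recognition site must be IUPAC DNA")

    @property
    def pattern(self) -> re.Pattern:
        # lookahead so overlapping occurrences are all reported;
        # classes never include N, so N in the sequence never matches
        body = "".join(f"[{_IUPAC[c]}]" for c in self.recognition_site)
        return re.compile(f"(?={body})")


ENZYMES = {
    "PstI": Enzyme("PstI", "CTGCAG", 5),
    "MseI": Enzyme("MseI", "TTAA", 1),
    "NsiI": Enzyme("NsiI", "ATGCAT", 5),
    "SbfI": Enzyme("SbfI", "CCTGCAGG", 6),
    "BfaI": Enzyme("BfaI", "CTAG", 1),
}


def find_sites(seq: str, enzyme: Enzyme) -> list[int]:
    """Ascending top-strand cut positions (site start + cut offset)."""
    seq = seq.upper()
    return [m.start() + enzyme.cut_offset
            for m in enzyme.pattern.finditer(seq)]


def double_digest(sequences: dict[str, str], rare: Enzyme, frequent: Enzyme,
                  methylation_fraction: float = 0.0,
                  seed: int = 0) -> pd.DataFrame:
    """Fragment each sequence at the pooled cut positions of two enzymes.

    Returns a frame (seq_id, start, end, left_enzyme, right_enzyme) with
    0-based half-open coordinates; sequence termini are labelled ``end``.
    A nonzero ``methylation_fraction`` removes that fraction of
    rare-cutter sites (seeded), emulating methylation insensitivity to
    cutting. If both enzymes cut at the same position the rare label wins.
    """
    if rare.name == frequent.name:
        raise ValueError("the two enzymes must be distinct")
    rng = np.random.default_rng(seed)
    rows = []
    for sid, seq in sequences.items():
        rare_cuts = np.array(find_sites(seq, rare), dtype=int)
        if methylation_fraction > 0 and rare_cuts.size:
            keep = rng.random(rare_cuts.size) >= methylation_fraction
            rare_cuts = rare_cuts[keep]
        freq_cuts = np.array(find_sites(seq, frequent), dtype=int)
        cuts = {int(c): rare.name for c in rare_cuts}
        for c in freq_cuts:
            cuts.setdefault(int(c), frequent.name)
        boundary = [(0, SEQUENCE_END)] + sorted(cuts.items()) \
            + [(len(seq), SEQUENCE_END)]
        for (s, left), (e, right) in zip(boundary[:-1], boundary[1:]):
            if e > s:
                rows.append((sid, s, e, left, right))
    return pd.DataFrame(rows, columns=["seq_id", "start", "end",
                                       "left_enzyme", "right_enzyme"])


def gbs_tags(fragments: pd.DataFrame, rare: Enzyme, frequent: Enzyme,
             min_len: int = 200, max_len: int = 500,
             hist_bins: int | np.ndarray = 20):
    """Size-selected mixed-end fragments (one rare + one frequent end).

    Returns (tag frame, tag count, (hist counts, hist edges)).
    """
    if min_len >= max_len:
        raise ValueError("min_len must be < max_len")
    length = fragments["end"] - fragments["start"]
    mixed = (((fragments["left_enzyme"] == rare.name)
              & (fragments["right_enzyme"] == frequent.name))
             | ((fragments["left_enzyme"] == frequent.name)
                & (fragments["right_enzyme"] == rare.name)))
    keep = mixed & (length >= min_len) & (length <= max_len)
    tags = fragments[keep].reset_index(drop=True)
    hist = np.histogram(length[keep], bins=hist_bins,
                        range=(min_len, max_len)
                        if np.isscalar(hist_bins) else None)
    return tags, int(keep.sum()), hist


def read_fasta(path) -> dict[str, str]:
    """Load a FASTA file as {id: sequence}."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
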