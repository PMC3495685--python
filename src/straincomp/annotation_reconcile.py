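"""Start-site reconciliation for homologous gene pairs with discrepant starts.

When two annotations of homologous genes disagree on the start coordinate
(same stop, different start), the choice cascades through: (1) exactly one
candidate has a plausible ribosome-binding site -> take it; (2) RBS status
ties and signal peptides are detected -> take the start placing the signal
peptide nearer the N-terminus; (3) otherwise take the longer ORF.

The RBS detector matches the Shine-Dalgarno consensus AGGAGG in the
-20..-5 window upstream of the candidate start; the signal-peptide
detector is a deliberate lightweight stand-in for SignalP-class tools: a
short strongly hydrophobic N-terminal window under the Kyte-Doolittle
scale.
"""
from __future__ import annotations

from dataclasses import dataclass

SD_CONSENSUS = "AGGAGG"
RBS_MIN_MATCH = 4
RBS_WINDOW = (-20, -5)  # bases relative to the start codon

#: Kyte & Doolittle hydropathy index
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9, "R": -4.5,
}
SIGNAL_WINDOW = 8
SIGNAL_SEARCH_LIMIT = 40
SIGNAL_MIN_HYDROPATHY = 1.5


@dataclass
class StartCandidate:
    """One candidate start coordinate for a gene with a fixed stop."""

    coordinate: int
    has_rbs: bool
    rbs_score: int
    signal_peptide_start: int | None  # 1-based residue index, None if absent
    orf_length: int  # bases

    @classmethod
    def evaluate(cls, coordinate: int, upstream: str, protein: str, orf_length: int) -> "StartCandidate":
        has_rbs, score = detect_rbs(upstream)
        return cls(coordinate, has_rbs, score, detect_signal_peptide(protein), orf_length)


def detect_rbs(upstream_sequence: str, consensus: str = SD_CONSENSUS, min_match: int = RBS_MIN_MATCH) -> tuple[bool, int]:
    """Longest run of the window matching a contiguous substring of the consensus.

    ``upstream_sequence`` is the -20..-5 window (strand-adjusted); a
    truncated window is scanned as available.  has_rbs requires a match of
    at least ``min_match`` consecutive bases.
    """
    window = upstream_sequence.upper()
    best = 0
    subs = {
        consensus[i : i + n]
        for n in range(1, len(consensus) + 1)
        for i in range(len(consensus) - n + 1)
    }
    for n in range(len(window), 0, -1):
        if any(window[i : i + n] in subs for i in range(len(window) - n + 1)):
            best = n
            break
    return best >= min_match, best


def detect_signal_peptide(protein: str) -> int | None:
    """1-based start of the first 8-residue window with mean KD hydropathy > 1.5.

    Only windows fully inside the N-terminal 40 residues are considered,
    starting after the initiator methionine (which is not part of the
    mature signal peptide); returns None when no such window exists.  The
    strict inequality means a window averaging exactly 1.5 does not
    qualify.
    """
    limit = min(len(protein), SIGNAL_SEARCH_LIMIT)
    for i in range(1, limit - SIGNAL_WINDOW + 1):
        window = protein[i : i + SIGNAL_WINDOW]
        mean = sum(KYTE_DOOLITTLE.get(aa, 0.0) for aa in window) / SIGNAL_WINDOW
        if mean > SIGNAL_MIN_HYDROPATHY:
            return i + 1
    return None


def resolve_start(candidate_1: StartCandidate, candidate_2: StartCandidate) -> tuple[StartCandidate, str]:
    """Apply the resolution cascade; returns (chosen candidate, rule applied).

    Rules: '1' = unique RBS, '2' = signal peptide nearer the N-terminus,
    '3' = longer ORF, 'none' = identical coordinates.
    """
    if candidate_1.coordinate == candidate_2.coordinate:
        return candidate_1, "none"
    if candidate_1.has_rbs != candidate_2.has_rbs:
        return (candidate_1 if candidate_1.has_rbs else candidate_2), "1"
    s1, s2 = candidate_1.signal_peptide_start, candidate_2.signal_peptide_start
    if s1 is not None or s2 is not None:
        if s1 is not None and (s2 is None or s1 < s2):
            return candidate_1, "2"
        if s2 is not None and (s1 is None or s2 < s1):
            return candidate_2, "2"
        # both detected at the same residue: fall through to ORF length
    if candidate_1.orf_length != candidate_2.orf_length:
        return (candidate_1 if candidate_1.orf_length > candidate_2.orf_length else candidate_2), "3"
    # same length, same evidence: deterministic tie-break on coordinate
    return (candidate_1 if candidate_1.coordinate < candidate_2.coordinate else candidate_2), "3"
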