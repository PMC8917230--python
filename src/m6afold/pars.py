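"""PARS scores from S1/V1 nuclease read-count tracks.

PARS (parallel analysis of RNA structure) contrasts double-strand-specific
V1 cleavage against single-strand-specific S1 cleavage:

    PARS_i = log2[ (V1_i * (S1_total / V1_total) + 5) / (S1_i + 5) ]

The S1_total/V1_total ratio normalises library depth and the pseudocount
of 5 keeps scores finite and damps positions with few reads.  High scores
indicate paired (helical) nucleotides, low scores unpaired ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

PSEUDOCOUNT = 5.0


@dataclass(frozen=True)
class NucleaseCounts:
    """Per-nucleotide V1/S1 read counts with library-wide totals."""

    v1: np.ndarray
    s1: np.ndarray
    v1_total: float | None = None
    s1_total: float | None = None

    def __post_init__(self):
        v1 = np.asarray(self.v1, dtype=float)
        s1 = np.asarray(self.s1, dtype=float)
        if v1.shape != s1.shape or v1.ndim != 1:
            raise ValueError("v1 and s1 must be 1-D arrays of equal length")
        if np.any(v1 < 0) or np.any(s1 < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "v1", v1)
        object.__setattr__(self, "s1", s1)
        # library totals default to the track sums but may exceed them
        vt = float(v1.sum()) if self.v1_total is None else float(self.v1_total)
        st = float(s1.sum()) if self.s1_total is None else float(self.s1_total)
        if vt <= 0 or st <= 0:
            raise ValueError("library totals must be positive")
        object.__setattr__(self, "v1_total", vt)
        object.__setattr__(self, "s1_total", st)


@dataclass(frozen=True)
class ParsTrack:
    scores: np.ndarray  # log2 units, one per nucleotide

    def __len__(self):
        return len(self.scores)


def pars_scores(counts: NucleaseCounts) -> ParsTrack:
    """Per-nucleotide PARS scores (finite everywhere by pseudocount)."""
    norm = counts.s1_total / counts.v1_total
    scores = np.log2((counts.v1 * norm + PSEUDOCOUNT)
                     / (counts.s1 + PSEUDOCOUNT))
    return ParsTrack(scores=scores)


def site_profile(track: ParsTrack, site: int, flank: int) -> dict[int, float]:
    """Scores around a 1-based site, keyed by offset -flank..+flank.

    Offsets falling outside the track are absent from the result.
    """
    n = len(track.scores)
    if not 1 <= site <= n:
        raise ValueError(f"site {site} outside track of length {n}")
    out = {}
    for off in range(-flank, flank + 1):
        pos = site + off
        if 1 <= pos <= n:
            out[off] = float(track.scores[pos - 1])
    return out


def mean_site_profile(tracks_and_sites, flank: int) -> dict[int, float]:
    """Position-wise mean profile over many (ParsTrack, site) pairs."""
    sums: dict[int, list] = {}
    for track, site in tracks_and_sites:
        for off, v in site_profile(track, site, flank).items():
            sums.setdefault(off, []).append(v)
    return {off: float(np.mean(v)) for off, v in sorted(sums.items())}
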