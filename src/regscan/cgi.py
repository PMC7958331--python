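"""CpG-island statistics and detection.

The island criterion is the classical one: a stretch whose G+C content
and observed/expected CpG ratio both clear thresholds over a minimum
length.  Obs/Exp CpG = #CpG / ((#C * #G) / N) over the region.  Detection
follows the CPGplot scheme: window statistics are averaged per position
over every window covering that position, positions whose averaged %GC
and averaged Obs/Exp both clear the thresholds (strict ``>``) form
candidate runs, and runs shorter than the minimum length are dropped.
The per-position averaging keeps island boundaries close to the true
CpG-dense core instead of smearing a full window length into the flanks.
Thresholds default to the published parameter set (Obs/Exp > 0.60,
%GC > 55, length > 200 bp); fixed-interval statistics are exact counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqcore import GenomicInterval, NucleotideSequence


@dataclass(frozen=True)
class CpGIslandParams:
    min_obs_exp: float = 0.60
    min_gc_percent: float = 55.0
    min_length: int = 200
    window: int = 100
    step: int = 1

    def __post_init__(self) -> None:
        if min(self.min_obs_exp, self.min_gc_percent, self.min_length, self.window, self.step) <= 0:
            raise ValueError("all CpG-island parameters must be strictly positive")
        if self.min_length < self.window:
            raise ValueError(f"min_length {self.min_length} < window {self.window}")


@dataclass(frozen=True)
class RegionCpGStats:
    interval: GenomicInterval
    gc_percent: float
    obs_exp_cpg: float


@dataclass(frozen=True)
class CpGIsland:
    interval: GenomicInterval
    stats: RegionCpGStats


def _counts(text: str) -> tuple[int, int, int]:
    """(#C, #G, #CpG) over an uppercase string; ambiguity codes count as neither."""
    c = text.count("C")
    g = text.count("G")
    cpg = text.count("CG")  # CG occurrences cannot overlap, count() is exact
    return c, g, cpg


def region_stats(seq: NucleotideSequence, iv: GenomicInterval | None = None) -> RegionCpGStats:
    """%GC and Obs/Exp CpG for an interval (default: the whole sequence).

    Obs/Exp is defined as 0 when the region has no C or no G.  U is
    treated as T, so the statistics are alphabet-invariant.
    """
    text = seq.as_dna().residues
    if iv is None:
        iv = GenomicInterval(seq.identifier, 1, len(text)) if text else None
        if iv is None:
            raise ValueError("empty sequence has no region statistics")
    if iv.end > len(text):
        raise ValueError(f"interval {iv} out of bounds for {seq.identifier!r} (length {len(text)})")
    sub = text[iv.start - 1 : iv.end]
    n = len(sub)
    c, g, cpg = _counts(sub)
    gc_percent = 100.0 * (c + g) / n
    obs_exp = 0.0 if c * g == 0 else cpg / ((c * g) / n)
    return RegionCpGStats(iv, gc_percent, obs_exp)


def detect_islands(seq: NucleotideSequence, params: CpGIslandParams | None = None) -> list[CpGIsland]:
    """Sliding-window island detection with per-position averaging.

    Window %GC and Obs/Exp are computed at every window start (step 1 for
    the averaging regardless of ``params.step``), each position is scored
    with the mean over all windows covering it, positions whose averaged
    values clear both thresholds form candidate runs, and runs shorter
    than ``min_length`` are dropped.  Reported islands carry whole-island
    statistics re-measured over the final interval.
    """
    if params is None:
        params = CpGIslandParams()
    text = seq.as_dna().residues
    n = len(text)
    w = params.window
    if n < w:
        return []

    # prefix sums for O(1) window counts
    arr = np.frombuffer(text.encode(), dtype=np.uint8)
    is_c = arr == ord("C")
    is_g = arr == ord("G")
    is_cpg = np.zeros(n, dtype=bool)
    if n > 1:
        is_cpg[:-1] = is_c[:-1] & is_g[1:]
    pc = np.concatenate(([0], np.cumsum(is_c)))
    pg = np.concatenate(([0], np.cumsum(is_g)))
    pcpg = np.concatenate(([0], np.cumsum(is_cpg)))

    starts = np.arange(0, n - w + 1)
    ends = starts + w  # exclusive
    c = pc[ends] - pc[starts]
    g = pg[ends] - pg[starts]
    # CpG dinucleotides fully inside the window: first base in [start, end-1)
    cpg = pcpg[ends - 1] - pcpg[starts]
    gc_pct = 100.0 * (c + g) / w
    with np.errstate(divide="ignore", invalid="ignore"):
        obs_exp = np.where(c * g > 0, cpg * w / np.maximum(c * g, 1), 0.0)

    # per-position mean over the windows covering each position
    def position_means(window_vals: np.ndarray) -> np.ndarray:
        cums = np.concatenate(([0.0], np.cumsum(window_vals)))
        lo = np.maximum(np.arange(n) - w + 1, 0)  # first covering window start
        hi = np.minimum(np.arange(n), n - w)      # last covering window start
        return (cums[hi + 1] - cums[lo]) / (hi - lo + 1)

    mean_gc = position_means(gc_pct)
    mean_oe = position_means(obs_exp)
    passing = (mean_gc > params.min_gc_percent) & (mean_oe > params.min_obs_exp)

    islands: list[CpGIsland] = []
    run_start: int | None = None
    for idx in range(n + 1):
        if idx < n and passing[idx]:
            if run_start is None:
                run_start = idx
        elif run_start is not None:
            if idx - run_start >= params.min_length:
                iv = GenomicInterval(seq.identifier, run_start + 1, idx)
                islands.append(CpGIsland(iv, region_stats(seq, iv)))
            run_start = None
    return islands
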