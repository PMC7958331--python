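"""miRNA recognition-element (MRE) prediction.

Finds the energetically most favorable intermolecular hybridizations of a
short RNA (a mature miRNA) against a long RNA (an mRNA), in the style of
duplex-only target predictors:

* a dynamic program over (miR position, target position) computes the
  minimum-free-energy duplex allowing Watson-Crick and G:U wobble pairs,
  bulges and internal loops — but no intramolecular pairs on either
  strand and no crossing pairs (the two strands are antiparallel);
* optimal and additional suboptimal, non-overlapping sites are reported
  up to a user-defined count threshold;
* significance comes from extreme-value (Gumbel) statistics of
  length-normalized minimum free energies calibrated on
  dinucleotide-shuffled targets, plus a Poisson tail for multiple sites;
* sites are mapped onto transcript features (5'UTR / exons / CDS / 3'UTR).

The energy model is a deliberately simple per-pair scheme (defaults:
GC -3.0, AU -2.0, GU -1.0 kcal/mol; affine bulge and internal-loop
penalties), not the full nearest-neighbor stacking tables; it is
user-overridable via :class:`EnergyModel`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import stats

from .seqcore import FeatureAnnotation, GenomicInterval, NucleotideSequence

logger = logging.getLogger(__name__)

_EULER_GAMMA = 0.5772156649015329

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3}


@dataclass(frozen=True)
class MatureMiR:
    """A mature miRNA, 5'->3', RNA alphabet."""

    identifier: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper().replace("T", "U")
        object.__setattr__(self, "sequence", seq)
        if len(seq) < 6:
            raise ValueError(f"{self.identifier}: miR shorter than 6 nt")
        bad = set(seq) - set("ACGUN")
        if bad:
            raise ValueError(f"{self.identifier}: non-RNA characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class EnergyModel:
    """Per-pair duplex energies (kcal/mol, negative) and loop penalties (positive)."""

    gc: float = -3.0
    au: float = -2.0
    gu: float = -1.0
    bulge_open: float = 3.0
    bulge_extend: float = 0.5
    internal_open: float = 2.0
    internal_extend: float = 0.5
    max_bulge: int = 15

    def __post_init__(self) -> None:
        if not (self.gc < 0 and self.au < 0 and self.gu < 0):
            raise ValueError("pair energies must be negative")
        if min(self.bulge_open, self.bulge_extend, self.internal_open, self.internal_extend) <= 0:
            raise ValueError("loop penalties must be positive")
        if self.max_bulge < 1:
            raise ValueError("max_bulge must be >= 1")

    def pair_energy(self, a: str, b: str) -> float:
        """Energy of pairing base *a* (miR) with base *b* (target); +inf if unpairable."""
        pair = {frozenset(("G", "C")): self.gc, frozenset(("A", "U")): self.au,
                frozenset(("G", "U")): self.gu}.get(frozenset((a, b)))
        return math.inf if pair is None else pair

    def loop_penalty(self, gap_mir: int, gap_target: int) -> float:
        """Penalty between consecutive pairs with the given unpaired counts."""
        if gap_mir == 0 and gap_target == 0:
            return 0.0
        if gap_mir > self.max_bulge or gap_target > self.max_bulge:
            return math.inf
        total = gap_mir + gap_target
        if gap_mir == 0 or gap_target == 0:
            return self.bulge_open + self.bulge_extend * (total - 1)
        return self.internal_open + self.internal_extend * (total - 2)


@dataclass(frozen=True)
class HybridizationSite:
    mir_id: str
    target_id: str
    target_interval: GenomicInterval  # transcript-local, 1-based
    mfe: float
    duplex_structure: tuple[tuple[int, int], ...]  # (mir_pos, target_pos), 1-based
    p_value: float | None = None
    feature_label: str | None = None

    @property
    def leftmost(self) -> int:
        return self.target_interval.start


@dataclass(frozen=True)
class EvdCalibration:
    """Gumbel fit of the null distribution of length-normalized best scores."""

    location: float
    scale: float
    normalization: str = "length-normalized MFE: x = -mfe / ln(m*n)"
    shuffle_count: int = 0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("Gumbel scale must be positive")


# ---------------------------------------------------------------------------
# encoding and DP kernel
# ---------------------------------------------------------------------------

def _encode_rna(residues: str) -> np.ndarray:
    """A/C/G/U(T) -> 0..3; anything else (N, ambiguity) -> -1 (unpairable)."""
    return np.array([_BASE_CODE.get(c, -1) for c in residues], dtype=np.int8)


def _pair_table(model: EnergyModel) -> np.ndarray:
    t = np.full((4, 4), np.inf)
    t[2, 1] = t[1, 2] = model.gc
    t[0, 3] = t[3, 0] = model.au
    t[2, 3] = t[3, 2] = model.gu
    return t


@njit(cache=True)
def _duplex_dp(mir, tar, pair, b_open, b_ext, i_open, i_ext, maxb):  # pragma: no cover - numba
    """Fill E[i,j] = best energy of a duplex whose last pair is (mir i, target j).

    Pairs are antiparallel and non-crossing: successive pairs have
    increasing miR index and decreasing target index.  Back-pointers
    (bi, bj) record the previous pair, -1 marking a duplex start
    (dangling ends are free).
    """
    m = mir.shape[0]
    n = tar.shape[0]
    INF = np.inf
    E = np.full((m, n), INF)
    bi = np.full((m, n), -1, dtype=np.int32)
    bj = np.full((m, n), -1, dtype=np.int32)
    for i in range(m):
        a = mir[i]
        if a < 0:
            continue
        for j in range(n):
            b = tar[j]
            if b < 0:
                continue
            pe = pair[a, b]
            if pe == INF:
                continue
            best = 0.0  # start a new duplex here
            pbi = -1
            pbj = -1
            ilo = i - 1 - maxb
            if ilo < 0:
                ilo = 0
            for ip in range(ilo, i):
                ga = i - ip - 1
                jhi = j + 1 + maxb
                if jhi > n - 1:
                    jhi = n - 1
                for jp in range(j + 1, jhi + 1):
                    if E[ip, jp] == INF:
                        continue
                    gb = jp - j - 1
                    if ga == 0 and gb == 0:
                        pen = 0.0
                    elif ga == 0 or gb == 0:
                        pen = b_open + b_ext * (ga + gb - 1)
                    else:
                        pen = i_open + i_ext * (ga + gb - 2)
                    cand = E[ip, jp] + pen
                    if cand < best:
                        best = cand
                        pbi = ip
                        pbj = jp
            E[i, j] = pe + best
            bi[i, j] = pbi
            bj[i, j] = pbj
    return E, bi, bj


def hybridize(
    mir: MatureMiR,
    target_window: NucleotideSequence,
    model: EnergyModel | None = None,
) -> tuple[float, tuple[tuple[int, int], ...]]:
    """Minimum-energy intermolecular duplex of *mir* against a target window.

    Returns ``(mfe, structure)`` where structure is a tuple of 1-based
    (mir_position, target_position) pairs with miR positions ascending
    and target positions descending (antiparallel).  DNA targets are
    transcribed T->U with a logged notice.  If no pairing is favorable,
    returns ``(0.0, ())``.
    """
    if model is None:
        model = EnergyModel()
    if target_window.alphabet_kind == "DNA":
        logger.info("hybridize: DNA input %s auto-transcribed to RNA", target_window.identifier)
        target_window = target_window.as_rna()
    mirc = _encode_rna(mir.sequence)
    tarc = _encode_rna(target_window.residues)
    if len(tarc) == 0 or len(mirc) == 0:
        return 0.0, ()
    E, bi, bj = _duplex_dp(
        mirc, tarc, _pair_table(model),
        model.bulge_open, model.bulge_extend,
        model.internal_open, model.internal_extend, model.max_bulge,
    )
    flat = np.argmin(E)
    i, j = np.unravel_index(flat, E.shape)
    mfe = E[i, j]
    if not np.isfinite(mfe) or mfe >= 0:
        return 0.0, ()
    pairs = _traceback(int(i), int(j), bi, bj)
    pairs.reverse()
    return float(mfe), tuple(pairs)


def _traceback(i: int, j: int, bi: np.ndarray, bj: np.ndarray) -> list[tuple[int, int]]:
    pairs = []
    while i >= 0:
        pairs.append((i + 1, j + 1))
        i, j = int(bi[i, j]), int(bj[i, j])
    return pairs


def best_duplex_mfe(
    mir: MatureMiR, target: NucleotideSequence, model: EnergyModel | None = None
) -> float:
    """MFE of the best duplex anywhere on *target* (no structure traceback)."""
    if model is None:
        model = EnergyModel()
    mirc = _encode_rna(mir.sequence)
    tarc = _encode_rna(target.as_rna().residues)
    E, _, _ = _duplex_dp(
        mirc, tarc, _pair_table(model),
        model.bulge_open, model.bulge_extend,
        model.internal_open, model.internal_extend, model.max_bulge,
    )
    mfe = float(np.min(E))
    return mfe if np.isfinite(mfe) and mfe < 0 else 0.0


# ---------------------------------------------------------------------------
# seed matching
# ---------------------------------------------------------------------------

_RNA_COMP = {"A": "U", "C": "G", "G": "C", "U": "A", "N": "N"}
_GU_OK = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


def seed_sites(
    mir: MatureMiR,
    target: NucleotideSequence,
    seed_span: tuple[int, int] = (2, 8),
    allowed_classes: frozenset[str] = frozenset({"7mer"}),
) -> list[int]:
    """1-based target positions whose window base-pairs with the miR seed.

    The seed (miR positions *seed_span*, default 2-8) pairs the target in
    antiparallel orientation, i.e. the target site reads as the reverse
    complement of the seed.  Classes: ``7mer`` (full span, Watson-Crick),
    ``6mer`` (span shortened by one at the 3' end), ``GU-tolerant``
    (full span, G:U wobble allowed).
    """
    lo, hi = seed_span
    if not (1 <= lo <= hi <= len(mir)):
        raise ValueError(f"seed span {seed_span} outside miR of length {len(mir)}")
    tar = target.as_rna().residues
    out: set[int] = set()
    spans: list[tuple[int, int, bool]] = []
    if "7mer" in allowed_classes:
        spans.append((lo, hi, False))
    if "GU-tolerant" in allowed_classes:
        spans.append((lo, hi, True))
    if "6mer" in allowed_classes:
        spans.append((lo, max(lo, hi - 1), False))
    for a, b, wobble in spans:
        seed = mir.sequence[a - 1 : b]
        L = len(seed)
        for p in range(len(tar) - L + 1):
            # antiparallel: seed 5'->3' pairs the site window read 3'->5'
            rev = tar[p : p + L][::-1]
            if all((s, t) in _GU_OK if wobble else _RNA_COMP.get(s) == t
                   for s, t in zip(seed, rev)):
                out.add(p + 1)
    return sorted(out)


# ---------------------------------------------------------------------------
# transcript scanning
# ---------------------------------------------------------------------------

def scan_transcript(
    mir: MatureMiR,
    transcript: NucleotideSequence,
    model: EnergyModel | None = None,
    max_sites: int = 10,
    energy_cutoff: float = 0.0,
    exhaustive: bool = False,
    window_pad: int = 8,
) -> list[HybridizationSite]:
    """Optimal and suboptimal non-overlapping duplex sites on a transcript.

    Candidate windows are anchored at seed matches; when the transcript
    has no seed match (or ``exhaustive=True``) overlapping tiles covering
    the whole transcript are used instead.  Sites are selected greedily
    by ascending MFE subject to non-overlap of their target intervals,
    stopping at *max_sites*; only sites with ``mfe < energy_cutoff`` (and
    at least one pair) are reported.  Positions are 1-based on the
    transcript 5'->3'.
    """
    if model is None:
        model = EnergyModel()
    tx = transcript.as_rna()
    m = len(mir)
    n = len(tx.residues)
    if n < m:
        return []
    windows: list[int] = []  # 0-based window starts
    wlen = min(n, m + 2 * window_pad)
    anchors = [] if exhaustive else seed_sites(mir, tx)
    if anchors and not exhaustive:
        for p in anchors:
            start = max(0, min(p - 1 - m - window_pad, n - wlen))
            windows.append(start)
    else:
        step = max(1, wlen - m)
        windows = list(range(0, max(1, n - wlen + 1), step))
        if windows[-1] != n - wlen:
            windows.append(n - wlen)
    candidates: dict[tuple[int, int], HybridizationSite] = {}
    for w0 in sorted(set(windows)):
        sub = NucleotideSequence(tx.identifier, tx.residues[w0 : w0 + wlen], "RNA")
        mfe, structure = hybridize(mir, sub, model)
        if not structure or mfe >= energy_cutoff:
            continue
        t_positions = [w0 + t for _, t in structure]  # 1-based transcript coords
        iv = GenomicInterval(tx.identifier, min(t_positions), max(t_positions), "+")
        shifted = tuple((mi, w0 + ti) for mi, ti in structure)
        key = (iv.start, iv.end)
        site = HybridizationSite(mir.identifier, tx.identifier, iv, mfe, shifted)
        prev = candidates.get(key)
        if prev is None or site.mfe < prev.mfe:
            candidates[key] = site
    ranked = sorted(candidates.values(), key=lambda s: (s.mfe, s.leftmost))
    chosen: list[HybridizationSite] = []
    for site in ranked:
        if len(chosen) >= max_sites:
            break
        if any(site.target_interval.overlaps(c.target_interval) for c in chosen):
            continue
        chosen.append(site)
    chosen.sort(key=lambda s: s.leftmost)
    return chosen


# ---------------------------------------------------------------------------
# null model and significance
# ---------------------------------------------------------------------------

def dinucleotide_shuffle(residues: str, rng: np.random.Generator) -> str:
    """Altschul-Erikson dinucleotide-preserving shuffle.

    Preserves the exact dinucleotide count multiset (hence mono-nucleotide
    composition and CpG-style stacking statistics) by taking a random
    Eulerian path through the dinucleotide multigraph.
    """
    s = residues
    if len(s) < 3:
        return s
    vertices = sorted(set(s))
    edges: dict[str, list[str]] = {v: [] for v in vertices}
    for a, b in zip(s, s[1:]):
        edges[a].append(b)
    last = s[-1]
    # pick a random last-edge per non-terminal vertex so that last-edges
    # form a tree rooted at the terminal vertex (guarantees Eulerian path)
    while True:
        last_edge = {}
        for v in vertices:
            if v == last or not edges[v]:
                continue
            last_edge[v] = edges[v][rng.integers(len(edges[v]))]
        ok = True
        for v in last_edge:
            seen = {v}
            cur = v
            while cur != last:
                nxt = last_edge.get(cur)
                if nxt is None or nxt in seen:
                    ok = False
                    break
                seen.add(nxt)
                cur = nxt
            if not ok:
                break
        if ok:
            break
    out_lists = {}
    for v in vertices:
        rest = list(edges[v])
        if v in last_edge:
            rest.remove(last_edge[v])
        rng.shuffle(rest)
        if v in last_edge:
            rest.append(last_edge[v])
        out_lists[v] = rest
    result = [s[0]]
    cur = s[0]
    idx = {v: 0 for v in vertices}
    for _ in range(len(s) - 1):
        nxt = out_lists[cur][idx[cur]]
        idx[cur] += 1
        result.append(nxt)
        cur = nxt
    return "".join(result)


def normalized_score(mfe: float, mir_length: int, target_length: int) -> float:
    """Length-normalized score x = -mfe / ln(m*n)."""
    return -mfe / math.log(mir_length * target_length)


def calibrate_evd(
    mir: MatureMiR,
    background: NucleotideSequence,
    model: EnergyModel | None = None,
    shuffle_count: int = 500,
    rng_seed: int = 0,
) -> EvdCalibration:
    """Fit a Gumbel null for best-site normalized scores.

    Generates *shuffle_count* dinucleotide-preserving shuffles of
    *background*, computes the best-duplex normalized score on each, and
    fits Gumbel location/scale by the method of moments
    (scale = std*sqrt(6)/pi, location = mean - gamma*scale).
    """
    if shuffle_count < 100:
        raise ValueError("shuffle_count must be >= 100 for a stable fit")
    if model is None:
        model = EnergyModel()
    rng = np.random.default_rng(rng_seed)
    bg = background.as_rna()
    m, n = len(mir), len(bg.residues)
    scores = np.empty(shuffle_count)
    for k in range(shuffle_count):
        shuf = NucleotideSequence(f"{bg.identifier}|shuf{k}", dinucleotide_shuffle(bg.residues, rng), "RNA")
        scores[k] = normalized_score(best_duplex_mfe(mir, shuf, model), m, n)
    std = float(np.std(scores, ddof=1))
    if std <= 1e-9 * max(1.0, abs(float(np.mean(scores)))):
        raise ValueError("degenerate background: zero variance of null scores")
    scale = std * math.sqrt(6.0) / math.pi
    location = float(np.mean(scores)) - _EULER_GAMMA * scale
    return EvdCalibration(location, scale, shuffle_count=shuffle_count, rng_seed=rng_seed)


def site_pvalue(
    site: HybridizationSite | float,
    cal: EvdCalibration,
    mir_length: int | None = None,
    target_length: int | None = None,
) -> float:
    """Gumbel upper-tail p-value of a site's length-normalized score.

    Accepts either a HybridizationSite plus the (m, n) lengths, or a
    pre-computed normalized score.
    """
    if isinstance(site, HybridizationSite):
        if mir_length is None or target_length is None:
            raise ValueError("mir_length and target_length required to normalize a site's MFE")
        x = normalized_score(site.mfe, mir_length, target_length)
    else:
        x = float(site)
    return float(1.0 - math.exp(-math.exp(-(x - cal.location) / cal.scale)))


def multi_site_pvalue(site_count: int, expected_rate: float) -> float:
    """P(K >= site_count) for K ~ Poisson(expected_rate)."""
    if expected_rate <= 0:
        raise ValueError("expected_rate must be positive")
    if site_count < 0:
        raise ValueError("site_count must be non-negative")
    if site_count == 0:
        return 1.0
    return float(stats.poisson.sf(site_count - 1, expected_rate))


# ---------------------------------------------------------------------------
# feature mapping and rendering
# ---------------------------------------------------------------------------

def map_to_features(
    sites: list[HybridizationSite], ann: FeatureAnnotation
) -> list[HybridizationSite]:
    """Label each site by the feature containing its leftmost position."""
    labeled = []
    for site in sites:
        label = ann.label_at(site.leftmost)
        if label is None:
            logger.warning(
                "site at %d of %s outside annotation span of %s",
                site.leftmost, site.target_id, ann.transcript_id,
            )
            label = "unannotated"
        labeled.append(
            HybridizationSite(
                site.mir_id, site.target_id, site.target_interval,
                site.mfe, site.duplex_structure, site.p_value, label,
            )
        )
    return labeled


def feature_counts(sites: list[HybridizationSite]) -> dict[str, int]:
    """Per-feature site counts (table layout: feature label -> number of MREs)."""
    counts: dict[str, int] = {}
    for site in sites:
        label = site.feature_label or "unannotated"
        counts[label] = counts.get(label, 0) + 1
    return counts


def render_duplex(mir: MatureMiR, target: NucleotideSequence, site: HybridizationSite) -> str:
    """Two-strand text rendering of a duplex (target 5'->3' over miR 3'->5')."""
    tar = target.as_rna().residues
    pairs = dict((t, m) for m, t in site.duplex_structure)
    t0, t1 = site.target_interval.start, site.target_interval.end
    top = []
    bonds = []
    bottom = []
    mir_positions = [pairs.get(t) for t in range(t0, t1 + 1)]
    for t in range(t0, t1 + 1):
        top.append(tar[t - 1])
        mp = pairs.get(t)
        if mp is not None:
            bonds.append("|")
            bottom.append(mir.sequence[mp - 1])
        else:
            bonds.append(" ")
            bottom.append("-")
    return (
        f"target 5' {''.join(top)} 3'  [{t0}-{t1}]\n"
        f"          {''.join(bonds)}\n"
        f"miR    3' {''.join(bottom)} 5'  ({mir.identifier}, {site.mfe:.1f} kcal/mol)"
    )
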