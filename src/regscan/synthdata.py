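"""Seeded synthetic sequences with planted regulatory structure.

Generates GC-controlled i.i.d. (or dinucleotide-aware, for CpG realism)
background DNA and writes planted features — consensus-motif instances
with a chosen mismatch count, CpG-island blocks with target %GC and
Obs/Exp CpG, spaced-dimer sites with per-half mismatches, and miRNA
complementary sites with a chosen fidelity — each recorded as a
ground-truth interval.  Every detector in the package can therefore be
exercised closed-loop against known truth without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .motifscan import iupac_match
from .seqcore import (
    IUPAC_CODES,
    GenomicInterval,
    NucleotideSequence,
    reverse_complement_str,
    write_bed,
    write_fasta,
)

_BASES = "ACGT"


@dataclass(frozen=True)
class MotifPlant:
    name: str
    pattern: str
    position: int  # 1-based start
    mismatches: int = 0


@dataclass(frozen=True)
class CgiPlant:
    name: str
    position: int
    length: int
    gc_fraction: float = 0.70
    obs_exp: float = 0.80
    max_tries: int = 1000


@dataclass(frozen=True)
class DimerPlant:
    name: str
    position: int
    spacer: int = 0
    mm_half1: int = 0
    mm_half2: int = 0
    half_pattern: str = "RRRCWWGYYY"


@dataclass(frozen=True)
class MrePlant:
    """Plants the reverse complement of a miR (a perfect or degraded target site)."""

    name: str
    position: int
    mir_sequence: str  # RNA 5'->3'
    fidelity: float = 1.0  # fraction of positions kept complementary


@dataclass(frozen=True)
class TruthRecord:
    name: str
    kind: str
    interval: GenomicInterval
    detail: str = ""


@dataclass
class SimulationSpec:
    rng_seed: int
    length: int
    gc_fraction: float = 0.5
    sequence_name: str = "synth"
    plants: list[MotifPlant | CgiPlant | DimerPlant | MrePlant] = field(default_factory=list)
    allow_overlap: bool = False

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("length must be positive")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must lie in [0, 1]")


def plant_mismatched_instance(pattern: str, k: int, rng: np.random.Generator | int) -> str:
    """A concrete string matching *pattern* at exactly (length - k) positions.

    Each non-mismatched position is a uniformly drawn base allowed by the
    IUPAC code; each of the *k* mismatch positions draws a base outside
    the code's set.  Positions whose code is N cannot be mismatched; if
    fewer than *k* positions are mismatchable, raises ValueError.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    pattern = pattern.upper()
    if not 0 <= k <= len(pattern):
        raise ValueError(f"mismatch count {k} outside [0, {len(pattern)}]")
    mismatchable = [i for i, c in enumerate(pattern) if c != "N"]
    if len(mismatchable) < k:
        raise ValueError(f"pattern {pattern!r} has only {len(mismatchable)} mismatchable positions, need {k}")
    mm_pos = set(rng.choice(mismatchable, size=k, replace=False)) if k else set()
    out = []
    for i, code in enumerate(pattern):
        allowed = sorted(IUPAC_CODES[code])
        if i in mm_pos:
            forbidden = set(allowed)
            choices = [b for b in _BASES if b not in forbidden]
            out.append(choices[rng.integers(len(choices))])
        else:
            out.append(allowed[rng.integers(len(allowed))])
    inst = "".join(out)
    assert sum(0 if iupac_match(b, c) else 1 for b, c in zip(inst, pattern)) == k
    return inst


def _random_background(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length, p=p)


def _cgi_block(rng: np.random.Generator, plant: CgiPlant) -> str:
    """Order-1 sampling toward target %GC and Obs/Exp, with rejection.

    After a C the G probability is scaled by the target Obs/Exp (CpG
    enrichment or depletion), which sets the dinucleotide statistic;
    rejection sampling then enforces block-level %GC within +/-2 points
    and Obs/Exp within +/-0.05 of target.
    """
    gc, oe, L = plant.gc_fraction, plant.obs_exp, plant.length
    p_plain = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    pg_after_c = min(0.95, oe * gc / 2)
    rest = 1.0 - pg_after_c - gc / 2  # C keeps its share; A/T absorb the rest
    p_after_c = np.array([rest / 2, gc / 2, pg_after_c, rest / 2])
    for _ in range(plant.max_tries):
        out = np.empty(L, dtype="<U1")
        prev_c = False
        for i in range(L):
            p = p_after_c if prev_c else p_plain
            b = _BASES[rng.choice(4, p=p)]
            out[i] = b
            prev_c = b == "C"
        block = "".join(out)
        n_c, n_g = block.count("C"), block.count("G")
        gc_pct = 100.0 * (n_c + n_g) / L
        obs_exp = 0.0 if n_c * n_g == 0 else block.count("CG") / ((n_c * n_g) / L)
        if abs(gc_pct - 100 * gc) <= 2.0 and abs(obs_exp - oe) <= 0.05:
            return block
    raise RuntimeError(
        f"CGI plant {plant.name!r}: could not hit %GC={100*gc:.1f}+/-2, "
        f"Obs/Exp={oe:.2f}+/-0.05 in {plant.max_tries} tries"
    )


def _realize(plant, rng: np.random.Generator) -> tuple[str, str, str]:
    """Return (concrete string, kind, detail) for a plant directive."""
    if isinstance(plant, MotifPlant):
        inst = plant_mismatched_instance(plant.pattern, plant.mismatches, rng)
        return inst, "motif", f"pattern={plant.pattern};mm={plant.mismatches}"
    if isinstance(plant, CgiPlant):
        block = _cgi_block(rng, plant)
        return block, "cgi", f"gc={plant.gc_fraction};obs_exp={plant.obs_exp}"
    if isinstance(plant, DimerPlant):
        h1 = plant_mismatched_instance(plant.half_pattern, plant.mm_half1, rng)
        h2 = plant_mismatched_instance(plant.half_pattern, plant.mm_half2, rng)
        spacer = "".join(_BASES[rng.integers(4)] for _ in range(plant.spacer))
        return h1 + spacer + h2, "dimer", (
            f"spacer={plant.spacer};mm={plant.mm_half1}+{plant.mm_half2}"
        )
    if isinstance(plant, MrePlant):
        mir_dna = plant.mir_sequence.upper().replace("U", "T")
        site = reverse_complement_str(mir_dna)
        n_mut = round((1.0 - plant.fidelity) * len(site))
        if n_mut:
            pos = rng.choice(len(site), size=n_mut, replace=False)
            site_l = list(site)
            for i in pos:
                site_l[i] = _BASES[(( _BASES.index(site_l[i]) + 1 + rng.integers(3)) % 4)]
            site = "".join(site_l)
        return site, "mre", f"mir={plant.mir_sequence};fidelity={plant.fidelity}"
    raise TypeError(f"unknown plant directive {type(plant).__name__}")


def generate(spec: SimulationSpec) -> tuple[NucleotideSequence, list[TruthRecord]]:
    """Background plus plants; identical outputs for identical specs.

    Raises before producing any output if a plant exceeds the sequence
    bounds or overlaps another plant (unless ``allow_overlap``).
    """
    rng = np.random.default_rng(spec.rng_seed)
    realized: list[tuple[int, str, str, str, str]] = []  # (pos0, string, name, kind, detail)
    for plant in spec.plants:
        s, kind, detail = _realize(plant, rng)
        pos0 = plant.position - 1
        if pos0 < 0 or pos0 + len(s) > spec.length:
            raise ValueError(
                f"plant {plant.name!r} spans [{plant.position}, {plant.position + len(s) - 1}] "
                f"outside sequence of length {spec.length}"
            )
        realized.append((pos0, s, plant.name, kind, detail))
    if not spec.allow_overlap:
        occupied = sorted((p, p + len(s), name) for p, s, name, _, _ in realized)
        for (s0, e0, n0), (s1, e1, n1) in zip(occupied, occupied[1:]):
            if s1 < e0:
                raise ValueError(f"plants {n0!r} and {n1!r} overlap")
    arr = _random_background(rng, spec.length, spec.gc_fraction)
    truth: list[TruthRecord] = []
    for pos0, s, name, kind, detail in realized:
        arr[pos0 : pos0 + len(s)] = np.frombuffer(s.encode(), dtype=np.uint8)
        truth.append(
            TruthRecord(
                name, kind,
                GenomicInterval(spec.sequence_name, pos0 + 1, pos0 + len(s), "+"),
                detail,
            )
        )
    seq = NucleotideSequence(spec.sequence_name, arr.tobytes().decode(), "DNA")
    truth.sort(key=lambda t: (t.interval.start, t.name))
    return seq, truth


def write_outputs(
    out_dir: str | Path, seq: NucleotideSequence, truth: list[TruthRecord]
) -> None:
    """FASTA + BED6 truth + TSV manifest of a simulation."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(out / "synthetic.fa", [seq])
    write_bed(out / "truth.bed", [(t.interval, f"{t.kind}:{t.name}", 0.0) for t in truth])
    with open(out / "truth.tsv", "w") as fh:
        fh.write("name\tkind\tstart\tend\tdetail\n")
        for t in truth:
            fh.write(f"{t.name}\t{t.kind}\t{t.interval.start}\t{t.interval.end}\t{t.detail}\n")
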