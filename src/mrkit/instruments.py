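"""Genetic-instrument selection and strength grading.

A variant qualifies as an instrument when it is robustly associated with the
exposure (genome-wide significance), approximately independent of the other
instruments (LD clumping), common enough to be well measured (MAF filter),
free of known confounder associations (exclusion list), and strong
(F statistic >= 10).  The per-SNP exposure variance explained is

    R^2 = 2 beta^2 EAF(1-EAF) / [2 beta^2 EAF(1-EAF) + se^2 * 2N * EAF(1-EAF)]
        = beta^2 / (beta^2 + se^2 * N)

and instrument strength is F = R^2 (N-2) / (1 - R^2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .summary_io import AssociationRecord, Exclusion, ReasonCode

__all__ = [
    "LDTable",
    "InstrumentDiagnostics",
    "significance_filter",
    "clump",
    "maf_filter",
    "find_proxy",
    "apply_exclusion_list",
    "variance_explained",
    "f_statistic",
    "grade_instruments",
    "weak_instrument_filter",
]


@dataclass
class LDTable:
    """Pairwise LD lookups (r-squared) keyed by unordered SNP-id pairs.

    An absent pair means r2 is unknown: treated as 0 for clumping and as
    "no proxy available" for proxy search.  r2(x, x) is 1 implicitly.
    """

    entries: dict[frozenset, float] = field(default_factory=dict)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str, float]]) -> "LDTable":
        table = cls()
        for a, b, r2 in pairs:
            table.set(a, b, r2)
        return table

    @classmethod
    def from_file(cls, path) -> "LDTable":
        frame = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
        cols = list(frame.columns[:3])
        return cls.from_pairs(
            (str(a), str(b), float(r))
            for a, b, r in frame[cols].itertuples(index=False)
        )

    def to_file(self, path) -> None:
        rows = [
            {"snp_a": a, "snp_b": b, "r2": r2}
            for (a, b), r2 in sorted(
                (tuple(sorted(k)), v) for k, v in self.entries.items()
            )
        ]
        pd.DataFrame(rows, columns=["snp_a", "snp_b", "r2"]).to_csv(
            path, sep="\t", index=False
        )

    def set(self, snp_a: str, snp_b: str, r2: float) -> None:
        if snp_a == snp_b:
            return
        if not (0.0 <= r2 <= 1.0):
            raise ValueError(f"r2 must be in [0, 1], got {r2} for ({snp_a}, {snp_b})")
        self.entries[frozenset((snp_a, snp_b))] = float(r2)

    def r2(self, snp_a: str, snp_b: str) -> float:
        if snp_a == snp_b:
            return 1.0
        return self.entries.get(frozenset((snp_a, snp_b)), 0.0)

    def known(self, snp_a: str, snp_b: str) -> bool:
        return snp_a == snp_b or frozenset((snp_a, snp_b)) in self.entries

    def partners(self, snp_id: str) -> dict[str, float]:
        out: dict[str, float] = {}
        for key, r2 in self.entries.items():
            if snp_id in key:
                (other,) = key - {snp_id}
                out[other] = r2
        return out


@dataclass(frozen=True)
class InstrumentDiagnostics:
    """Per-SNP strength summary and retention verdict."""

    snp_id: str
    r2_explained: float
    f_stat: float
    retained: bool
    reason: ReasonCode | None = None


def significance_filter(
    records: Sequence[AssociationRecord],
    p_threshold: float = 5e-8,
    ledger: list[Exclusion] | None = None,
) -> list[AssociationRecord]:
    """Keep records with p strictly below the genome-wide threshold."""
    kept = []
    for rec in records:
        if rec.pval < p_threshold:
            kept.append(rec)
        elif ledger is not None:
            ledger.append(
                Exclusion(rec.snp_id, ReasonCode.WEAK_INSTRUMENT, f"p={rec.pval:.3g} >= {p_threshold:g}")
            )
    return kept


def clump(
    records: Sequence[AssociationRecord],
    ld: LDTable,
    r2_threshold: float = 0.001,
    window_kb: float = 10_000,
    ledger: list[Exclusion] | None = None,
) -> list[AssociationRecord]:
    """Greedy LD clumping.

    Repeatedly takes the most significant unassigned SNP as an index and
    removes every unassigned SNP on the same chromosome within +-window_kb
    whose r2 with the index is >= ``r2_threshold`` (within an LD pair the
    lower-p SNP survives).  Ties in p are broken by snp_id.  Every record
    must carry chrom and pos.
    """
    for rec in records:
        if rec.chrom is None or rec.pos is None:
            raise ValueError(f"{rec.snp_id}: chrom/pos required for clumping")
    order = sorted(records, key=lambda r: (r.pval, r.snp_id))
    window_bp = window_kb * 1000.0
    assigned: dict[str, str | None] = {}  # snp -> index snp that removed it (None = index)
    for rec in order:
        if rec.snp_id in assigned:
            continue
        assigned[rec.snp_id] = None
        for other in order:
            if other.snp_id in assigned:
                continue
            if other.chrom != rec.chrom:
                continue
            if abs(other.pos - rec.pos) > window_bp:
                continue
            if ld.r2(rec.snp_id, other.snp_id) >= r2_threshold:
                assigned[other.snp_id] = rec.snp_id
    kept = [r for r in records if assigned[r.snp_id] is None]
    if ledger is not None:
        for rec in records:
            index_snp = assigned[rec.snp_id]
            if index_snp is not None:
                ledger.append(
                    Exclusion(rec.snp_id, ReasonCode.CLUMPED, f"in LD with {index_snp}")
                )
    return kept


def maf_filter(
    records: Sequence[AssociationRecord],
    maf_threshold: float = 0.01,
    ledger: list[Exclusion] | None = None,
) -> list[AssociationRecord]:
    """Remove records whose minor-allele frequency is below the threshold."""
    kept = []
    for rec in records:
        if rec.maf >= maf_threshold:
            kept.append(rec)
        elif ledger is not None:
            ledger.append(Exclusion(rec.snp_id, ReasonCode.MAF, f"MAF={rec.maf:.4g}"))
    return kept


def find_proxy(
    target_snp: str,
    outcome_records: Sequence[AssociationRecord],
    ld: LDTable,
    proxy_r2: float = 0.8,
) -> str | None:
    """Best available proxy in the outcome dataset, or None.

    Returns the outcome SNP with maximal r2 to the target among those with
    r2 strictly above ``proxy_r2``; ties broken by snp_id.
    """
    best: tuple[float, str] | None = None
    for rec in outcome_records:
        if rec.snp_id == target_snp:
            continue
        if not ld.known(target_snp, rec.snp_id):
            continue
        r2 = ld.r2(target_snp, rec.snp_id)
        if r2 > proxy_r2:
            # maximise r2; among equals prefer the lexicographically first id
            key = (r2, rec.snp_id)
            if best is None or r2 > best[0] or (r2 == best[0] and rec.snp_id < best[1]):
                best = key
    return None if best is None else best[1]


def apply_exclusion_list(
    records: Sequence[AssociationRecord],
    exclusions: Sequence[tuple[str, str]],
    ledger: list[Exclusion] | None = None,
) -> list[AssociationRecord]:
    """Remove SNPs named on a confounder exclusion list.

    ``exclusions`` pairs a snp_id with a free-text reason (e.g. the
    confounding trait it is associated with).  Naming an absent SNP is a
    warning, not an error.
    """
    present = {rec.snp_id for rec in records}
    notes: dict[str, str] = {}
    for snp_id, reason in exclusions:
        if snp_id not in present:
            warnings.warn(f"exclusion list names absent SNP {snp_id!r}", stacklevel=2)
            continue
        notes[snp_id] = reason
    kept = []
    for rec in records:
        if rec.snp_id in notes:
            if ledger is not None:
                ledger.append(Exclusion(rec.snp_id, ReasonCode.CONFOUNDER, notes[rec.snp_id]))
        else:
            kept.append(rec)
    return kept


def variance_explained(beta: float, se: float, eaf: float, n: float) -> float:
    """Fraction of exposure variance explained by one SNP.

    2 beta^2 EAF(1-EAF) / [2 beta^2 EAF(1-EAF) + se^2 * 2N * EAF(1-EAF)],
    which simplifies algebraically to beta^2 / (beta^2 + se^2 * N).
    """
    if not (0.0 < eaf < 1.0):
        raise ValueError(f"eaf must be strictly inside (0, 1), got {eaf}")
    if se <= 0:
        raise ValueError(f"se must be > 0, got {se}")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    b2 = beta * beta
    return b2 / (b2 + se * se * n)


def f_statistic(r2_explained: float, n: float) -> float:
    """Instrument-strength F = R^2 (N-2) / (1 - R^2)."""
    if not (0.0 <= r2_explained < 1.0):
        raise ValueError(f"r2_explained must be in [0, 1), got {r2_explained}")
    if n <= 2:
        raise ValueError(f"n must exceed 2, got {n}")
    return r2_explained * (n - 2) / (1.0 - r2_explained)


def grade_instruments(
    records: Sequence[AssociationRecord],
    f_threshold: float = 10.0,
) -> list[InstrumentDiagnostics]:
    """Per-SNP R^2 / F and a weak-instrument verdict (F >= threshold keeps)."""
    out = []
    for rec in records:
        r2 = variance_explained(rec.beta, rec.se, rec.eaf, rec.n)
        f = f_statistic(r2, rec.n)
        weak = f < f_threshold
        out.append(
            InstrumentDiagnostics(
                snp_id=rec.snp_id,
                r2_explained=r2,
                f_stat=f,
                retained=not weak,
                reason=ReasonCode.WEAK_INSTRUMENT if weak else None,
            )
        )
    return out


def weak_instrument_filter(
    records: Sequence[AssociationRecord],
    f_threshold: float = 10.0,
    ledger: list[Exclusion] | None = None,
) -> list[AssociationRecord]:
    """Drop instruments with F below the threshold (F >= threshold retained)."""
    diags = {d.snp_id: d for d in grade_instruments(records, f_threshold)}
    kept = []
    for rec in records:
        d = diags[rec.snp_id]
        if d.retained:
            kept.append(rec)
        elif ledger is not None:
            ledger.append(
                Exclusion(rec.snp_id, ReasonCode.WEAK_INSTRUMENT, f"F={d.f_stat:.2f}")
            )
    return kept
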