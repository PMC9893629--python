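"""Read, write and harmonize GWAS summary statistics.

Two-sample MR works from per-SNP association tables: one row per variant
holding the effect allele, the other allele, the effect-allele frequency
(EAF), the additive effect on the trait (log-odds scale for binary traits),
its standard error, p-value and sample size.  Before any causal estimate can
be formed, the exposure and outcome tables must be *harmonized* so that both
effects refer to the same effect allele of each SNP; this module implements
the standard swap / strand-complement / palindrome rules and keeps an
explicit ledger of every SNP it drops and why.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AssociationRecord",
    "ReasonCode",
    "Exclusion",
    "HarmonizedSet",
    "ConfigurationError",
    "TableParseError",
    "read_gwas_table",
    "write_gwas_table",
    "is_palindromic",
    "complement_allele",
    "harmonize",
    "as_effect_arrays",
]

_NUCLEOTIDES = {"A", "C", "G", "T"}
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class ConfigurationError(ValueError):
    """A column mapping or config does not resolve a required field."""


class TableParseError(ValueError):
    """One or more rows of a summary-statistics table are invalid."""

    def __init__(self, problems: list[str]):
        self.problems = list(problems)
        super().__init__(
            "invalid rows in summary-statistics table:\n  " + "\n  ".join(problems)
        )


class ReasonCode(str, enum.Enum):
    """Why a SNP left the instrument set; the FIRST failing rule wins."""

    MISSING_IN_OUTCOME = "MISSING_IN_OUTCOME"
    PALINDROMIC = "PALINDROMIC"
    INCOMPATIBLE_ALLELES = "INCOMPATIBLE_ALLELES"
    CONFOUNDER = "CONFOUNDER"
    WEAK_INSTRUMENT = "WEAK_INSTRUMENT"
    MAF = "MAF"
    CLUMPED = "CLUMPED"


@dataclass(frozen=True)
class Exclusion:
    snp_id: str
    reason: ReasonCode
    note: str = ""


@dataclass(frozen=True)
class AssociationRecord:
    """One SNP's association with one trait.

    ``beta`` is the additive effect per copy of ``effect_allele``; for the
    binary traits this package targets it is on the log-odds scale.
    ``eaf`` is the effect-allele frequency.  ``chrom``/``pos`` (1-based) are
    optional but required for LD clumping.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pval: float
    n: int
    chrom: str | None = None
    pos: int | None = None
    n_cases: int | None = None
    annotations: Mapping[str, object] = field(default_factory=dict, compare=False)

    def validate(self) -> None:
        if not self.snp_id:
            raise ValueError("snp_id must be non-empty")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: effect and other allele are identical")
        if not (self.se > 0):
            raise ValueError(f"{self.snp_id}: se must be > 0 (got {self.se})")
        if not (0.0 <= self.eaf <= 1.0):
            raise ValueError(f"{self.snp_id}: eaf must be in [0, 1] (got {self.eaf})")
        if not (0.0 < self.pval <= 1.0):
            raise ValueError(f"{self.snp_id}: pval must be in (0, 1] (got {self.pval})")
        if self.n < 2:
            raise ValueError(f"{self.snp_id}: n must be >= 2 (got {self.n})")

    @property
    def maf(self) -> float:
        return min(self.eaf, 1.0 - self.eaf)

    @property
    def is_indel(self) -> bool:
        return not (
            self.effect_allele in _NUCLEOTIDES and self.other_allele in _NUCLEOTIDES
        )


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """True iff the unordered allele pair is {A,T} or {C,G}.

    Multi-character (indel) alleles are never palindromic.
    """
    pair = {str(effect_allele).upper(), str(other_allele).upper()}
    return pair == {"A", "T"} or pair == {"C", "G"}


def complement_allele(allele: str) -> str | None:
    """Complementary-strand base, or None for indels/ambiguity codes."""
    return _COMPLEMENT.get(str(allele).upper())


# canonical field -> default column header (matched case-insensitively)
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "snp_id": "SNP",
    "effect_allele": "EA",
    "other_allele": "NEA",
    "eaf": "EAF",
    "beta": "Beta",
    "se": "SE",
    "pval": "P",
    "n": "N",
    "chrom": "Ch",
    "pos": "Pos",
    "n_cases": "Ncases",
}

_REQUIRED_FIELDS = ("snp_id", "effect_allele", "other_allele", "eaf", "beta", "se", "pval", "n")
_OPTIONAL_FIELDS = ("chrom", "pos", "n_cases")
_NA_STRINGS = {"", "NA", "NaN", "nan", "None", "."}


def _detect_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def read_gwas_table(
    source,
    column_map: Mapping[str, str] | None = None,
) -> list[AssociationRecord]:
    """Read a tab- or comma-separated summary-statistics table.

    ``column_map`` maps canonical field names (``snp_id``, ``effect_allele``,
    ``other_allele``, ``eaf``, ``beta``, ``se``, ``pval``, ``n``, and
    optionally ``chrom``, ``pos``, ``n_cases``) to the file's column headers;
    unmapped fields fall back to the defaults (SNP, EA, NEA, EAF, Beta, SE,
    P, N, Ch, Pos, Ncases), matched case-insensitively.  Rows that violate
    record invariants or contain unparsable numbers raise
    :class:`TableParseError` naming the offending line.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text(encoding="utf-8")
    else:
        text = source.read()
    if not text.strip():
        return []
    sep = _detect_delimiter(text.splitlines()[0])
    frame = pd.read_csv(io.StringIO(text), sep=sep, dtype=str, keep_default_na=False)

    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        unknown = set(column_map) - set(DEFAULT_COLUMN_MAP)
        if unknown:
            raise ConfigurationError(f"unknown field(s) in column_map: {sorted(unknown)}")
        cmap.update(column_map)

    lower_cols = {c.lower(): c for c in frame.columns}
    resolved: dict[str, str] = {}
    for field_name, col in cmap.items():
        actual = lower_cols.get(col.lower())
        if actual is not None:
            resolved[field_name] = actual
    missing = [f for f in _REQUIRED_FIELDS if f not in resolved]
    if missing:
        raise ConfigurationError(
            "missing required column(s): "
            + ", ".join(f"{f} (expected header '{cmap[f]}')" for f in missing)
        )

    records: list[AssociationRecord] = []
    problems: list[str] = []
    for i in range(len(frame)):
        line_no = i + 2  # header is line 1
        raw = {f: frame.iloc[i][resolved[f]] for f in resolved}
        try:
            kwargs: dict[str, object] = {
                "snp_id": str(raw["snp_id"]).strip(),
                "effect_allele": str(raw["effect_allele"]).strip().upper(),
                "other_allele": str(raw["other_allele"]).strip().upper(),
                "eaf": float(raw["eaf"]),
                "beta": float(raw["beta"]),
                "se": float(raw["se"]),
                "pval": float(raw["pval"]),
                "n": int(float(raw["n"])),
            }
            if "chrom" in raw and str(raw["chrom"]).strip() not in _NA_STRINGS:
                kwargs["chrom"] = str(raw["chrom"]).strip()
            if "pos" in raw and str(raw["pos"]).strip() not in _NA_STRINGS:
                kwargs["pos"] = int(float(raw["pos"]))
            if "n_cases" in raw and str(raw["n_cases"]).strip() not in _NA_STRINGS:
                kwargs["n_cases"] = int(float(raw["n_cases"]))
            rec = AssociationRecord(**kwargs)
            rec.validate()
            records.append(rec)
        except (ValueError, TypeError) as exc:
            problems.append(f"line {line_no}: {exc}")
    if problems:
        raise TableParseError(problems)
    return records


def write_gwas_table(records: Sequence[AssociationRecord], destination) -> None:
    """Write records as a tab-separated table; round-trips with
    :func:`read_gwas_table` field-for-field (floats use shortest repr)."""
    cols = ["SNP", "Ch", "Pos", "EA", "NEA", "EAF", "Beta", "SE", "P", "N", "Ncases"]
    rows = []
    for r in records:
        rows.append(
            {
                "SNP": r.snp_id,
                "Ch": r.chrom if r.chrom is not None else "NA",
                "Pos": r.pos if r.pos is not None else "NA",
                "EA": r.effect_allele,
                "NEA": r.other_allele,
                "EAF": repr(r.eaf),
                "Beta": repr(r.beta),
                "SE": repr(r.se),
                "P": repr(r.pval),
                "N": r.n,
                "Ncases": r.n_cases if r.n_cases is not None else "NA",
            }
        )
    frame = pd.DataFrame(rows, columns=cols)
    frame.to_csv(destination, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Harmonization
# ---------------------------------------------------------------------------

PAIR_COLUMNS = [
    "snp_id",
    "gamma",
    "se_gamma",
    "Gamma",
    "se_Gamma",
    "eaf_exposure",
    "eaf_outcome",
]


@dataclass
class HarmonizedSet:
    """Aligned exposure/outcome effect pairs sharing one effect allele.

    ``pairs`` columns: snp_id, gamma (exposure beta), se_gamma, Gamma
    (outcome beta), se_Gamma, eaf_exposure, eaf_outcome.  ``exclusions``
    records every exposure SNP that did not make it, with a reason code.
    """

    pairs: pd.DataFrame
    exclusions: list[Exclusion] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pairs = pd.DataFrame(self.pairs, columns=PAIR_COLUMNS).reset_index(drop=True)

    @classmethod
    def from_arrays(
        cls,
        gamma,
        se_gamma,
        Gamma,
        se_Gamma,
        snp_ids: Sequence[str] | None = None,
        eaf_exposure=None,
        eaf_outcome=None,
    ) -> "HarmonizedSet":
        gamma = np.asarray(gamma, dtype=float)
        j = gamma.size
        if snp_ids is None:
            snp_ids = [f"snp{i + 1}" for i in range(j)]
        frame = pd.DataFrame(
            {
                "snp_id": list(snp_ids),
                "gamma": gamma,
                "se_gamma": np.asarray(se_gamma, dtype=float),
                "Gamma": np.asarray(Gamma, dtype=float),
                "se_Gamma": np.asarray(se_Gamma, dtype=float),
                "eaf_exposure": np.full(j, np.nan) if eaf_exposure is None else np.asarray(eaf_exposure, dtype=float),
                "eaf_outcome": np.full(j, np.nan) if eaf_outcome is None else np.asarray(eaf_outcome, dtype=float),
            }
        )
        return cls(frame)

    @property
    def n_snps(self) -> int:
        return len(self.pairs)

    @property
    def snp_ids(self) -> np.ndarray:
        return self.pairs["snp_id"].to_numpy()

    @property
    def gamma(self) -> np.ndarray:
        return self.pairs["gamma"].to_numpy(dtype=float)

    @property
    def se_gamma(self) -> np.ndarray:
        return self.pairs["se_gamma"].to_numpy(dtype=float)

    @property
    def Gamma(self) -> np.ndarray:
        return self.pairs["Gamma"].to_numpy(dtype=float)

    @property
    def se_Gamma(self) -> np.ndarray:
        return self.pairs["se_Gamma"].to_numpy(dtype=float)

    def subset(self, index) -> "HarmonizedSet":
        """New set keeping rows selected by a boolean mask or index array."""
        mask = np.asarray(index)
        if mask.dtype == bool:
            kept = self.pairs.loc[mask]
        else:
            kept = self.pairs.iloc[mask]
        return HarmonizedSet(kept.reset_index(drop=True), list(self.exclusions))

    def drop_snp(self, snp_id: str) -> "HarmonizedSet":
        return self.subset(self.pairs["snp_id"].to_numpy() != snp_id)


def _index_by_snp(records: Iterable[AssociationRecord], label: str) -> dict[str, AssociationRecord]:
    out: dict[str, AssociationRecord] = {}
    for rec in records:
        if rec.snp_id in out:
            raise ValueError(f"duplicate snp_id {rec.snp_id!r} in {label} dataset")
        out[rec.snp_id] = rec
    return out


def _orient_outcome(
    exp: AssociationRecord, out: AssociationRecord
) -> tuple[float, float, float] | None:
    """Outcome (beta, se, eaf) expressed for the exposure's effect allele.

    Tries exact allele match, swapped alleles, then the same two options
    after complementary-strand substitution.  Returns None when the allele
    sets are irreconcilable.  Not for palindromic SNPs (callers handle those
    first: strand substitution is indistinguishable from a swap there).
    """
    ea, oa = exp.effect_allele, exp.other_allele
    for flip_strand in (False, True):
        oea, ooa = out.effect_allele, out.other_allele
        if flip_strand:
            c1, c2 = complement_allele(oea), complement_allele(ooa)
            if c1 is None or c2 is None:
                continue
            oea, ooa = c1, c2
        if (oea, ooa) == (ea, oa):
            return out.beta, out.se, out.eaf
        if (oea, ooa) == (oa, ea):
            return -out.beta, out.se, 1.0 - out.eaf
    return None


def harmonize(
    exposure: Sequence[AssociationRecord],
    outcome: Sequence[AssociationRecord],
    palindromic_mode: str = "drop",
    eaf_ambiguity_threshold: float = 0.42,
) -> HarmonizedSet:
    """Align outcome effects to the exposure's effect alleles.

    Rules, applied per exposure SNP found in the outcome:

    * identical alleles — keep as-is;
    * swapped alleles — negate the outcome beta, EAF becomes 1−EAF;
    * alleles matching only after complementary-strand substitution —
      substitute, then apply the two rules above;
    * palindromic SNPs (A/T or C/G) — dropped under ``palindromic_mode
      "drop"`` (the default, matching the conservative convention); under
      ``"infer"`` they are oriented by comparing allele frequencies on the
      two sides and dropped as ambiguous when either EAF lies within
      ``[t, 1−t]`` for ``t = eaf_ambiguity_threshold``;
    * anything irreconcilable — excluded as INCOMPATIBLE_ALLELES.

    SNPs absent from the outcome are excluded MISSING_IN_OUTCOME.  The
    exclusion ledger is exhaustive: retained + excluded == len(exposure).
    """
    if palindromic_mode not in ("drop", "infer"):
        raise ValueError(f"palindromic_mode must be 'drop' or 'infer', got {palindromic_mode!r}")
    out_by_id = _index_by_snp(outcome, "outcome")
    _index_by_snp(exposure, "exposure")  # duplicate check

    rows: list[dict[str, object]] = []
    exclusions: list[Exclusion] = []
    for exp in exposure:
        out = out_by_id.get(exp.snp_id)
        if out is None:
            exclusions.append(Exclusion(exp.snp_id, ReasonCode.MISSING_IN_OUTCOME))
            continue
        if is_palindromic(exp.effect_allele, exp.other_allele):
            if palindromic_mode == "drop":
                exclusions.append(
                    Exclusion(exp.snp_id, ReasonCode.PALINDROMIC, "palindromic allele pair")
                )
                continue
            # infer mode: allele labels carry no strand information for a
            # palindrome, so orientation rests on allele frequency alone.
            exp_pair = {exp.effect_allele, exp.other_allele}
            out_pair = {out.effect_allele, out.other_allele}
            if exp_pair != out_pair:
                exclusions.append(
                    Exclusion(exp.snp_id, ReasonCode.INCOMPATIBLE_ALLELES)
                )
                continue
            lo, hi = eaf_ambiguity_threshold, 1.0 - eaf_ambiguity_threshold
            if lo <= exp.eaf <= hi or lo <= out.eaf <= hi:
                exclusions.append(
                    Exclusion(exp.snp_id, ReasonCode.PALINDROMIC, "ambiguous EAF")
                )
                continue
            if (exp.eaf < 0.5) == (out.eaf < 0.5):
                Gamma, se_Gamma, eaf_out = out.beta, out.se, out.eaf
            else:
                Gamma, se_Gamma, eaf_out = -out.beta, out.se, 1.0 - out.eaf
        else:
            oriented = _orient_outcome(exp, out)
            if oriented is None:
                exclusions.append(Exclusion(exp.snp_id, ReasonCode.INCOMPATIBLE_ALLELES))
                continue
            Gamma, se_Gamma, eaf_out = oriented
        rows.append(
            {
                "snp_id": exp.snp_id,
                "gamma": exp.beta,
                "se_gamma": exp.se,
                "Gamma": Gamma,
                "se_Gamma": se_Gamma,
                "eaf_exposure": exp.eaf,
                "eaf_outcome": eaf_out,
            }
        )
    return HarmonizedSet(pd.DataFrame(rows, columns=PAIR_COLUMNS), exclusions)


def as_effect_arrays(data) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Coerce estimator input to (snp_ids, gamma, se_gamma, Gamma, se_Gamma).

    Accepts a :class:`HarmonizedSet`, a DataFrame with the pair columns, or
    an array of shape (J, 4) ordered (gamma, se_gamma, Gamma, se_Gamma).
    """
    if isinstance(data, HarmonizedSet):
        return data.snp_ids, data.gamma, data.se_gamma, data.Gamma, data.se_Gamma
    if isinstance(data, pd.DataFrame):
        ids = (
            data["snp_id"].to_numpy()
            if "snp_id" in data.columns
            else np.array([f"snp{i+1}" for i in range(len(data))])
        )
        return (
            ids,
            data["gamma"].to_numpy(dtype=float),
            data["se_gamma"].to_numpy(dtype=float),
            data["Gamma"].to_numpy(dtype=float),
            data["se_Gamma"].to_numpy(dtype=float),
        )
    arr = np.asarray(data, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 4:
        raise ValueError(
            "expected a HarmonizedSet, a pair DataFrame, or an array of shape (J, 4)"
        )
    ids = np.array([f"snp{i+1}" for i in range(arr.shape[0])])
    return ids, arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3]
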