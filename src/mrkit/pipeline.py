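"""Config-driven end-to-end two-sample MR analysis.

For each named outcome, the pipeline runs: genome-wide significance filter
-> LD clumping (when an LD table is supplied) -> MAF filter -> harmonization
with proxy substitution for SNPs missing from the outcome -> confounder
exclusion list -> instrument strength (R^2, F) and weak-instrument filter ->
all requested causal estimators -> heterogeneity / pleiotropy / outlier /
leave-one-out / funnel diagnostics -> binary-outcome power -> an evidence
grade with a Bonferroni-style threshold (alpha divided by the number of
outcomes).  Everything is deterministic given the config seed, and every
removed SNP carries exactly one first-cause reason in the ledger.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from .diagnostics import cochran_q, funnel_data, leave_one_out, mr_presso
from .estimators import (
    MREstimate,
    egger,
    estimates_table,
    ivw,
    weighted_median,
    weighted_mode,
)
from .instruments import (
    LDTable,
    apply_exclusion_list,
    clump,
    find_proxy,
    grade_instruments,
    maf_filter,
    significance_filter,
    weak_instrument_filter,
)
from .power import PowerQuery, mr_power_binary
from .summary_io import (
    AssociationRecord,
    Exclusion,
    HarmonizedSet,
    harmonize,
    read_gwas_table,
)

logger = logging.getLogger("mrkit")

__all__ = [
    "Thresholds",
    "OutcomeSpec",
    "AnalysisConfig",
    "OutcomeResult",
    "AnalysisReport",
    "classify_evidence",
    "select_instruments",
    "run_analysis",
    "run_bidirectional",
]

DEFAULT_METHODS = ("IVW_FE", "IVW_MRE", "EGGER", "WEIGHTED_MEDIAN", "WEIGHTED_MODE")


@dataclass(frozen=True)
class Thresholds:
    p_sig: float = 5e-8
    clump_r2: float = 0.001
    clump_window_kb: float = 10_000
    maf: float = 0.01
    proxy_r2: float = 0.8
    f_min: float = 10.0


@dataclass
class OutcomeSpec:
    """One outcome dataset plus the sample sizes its power calc needs."""

    data: Sequence[AssociationRecord] | str | Path
    n_total: int
    n_cases: int

    def records(self) -> list[AssociationRecord]:
        if isinstance(self.data, (str, Path)):
            return read_gwas_table(self.data)
        return list(self.data)


@dataclass
class AnalysisConfig:
    exposure: Sequence[AssociationRecord] | str | Path
    outcomes: Mapping[str, OutcomeSpec]
    seed: int
    ld: LDTable | str | Path | None = None
    exclusions: Sequence[tuple[str, str]] | str | Path | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    methods: Sequence[str] = DEFAULT_METHODS
    n_boot: int = 1000
    n_sim: int = 1000
    alpha: float = 0.05
    or_target: float = 1.3
    palindromic_mode: str = "drop"
    n_outcomes_for_correction: int | None = None

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text())
        base = Path(path).parent

        def resolve(p):
            p = Path(p)
            return p if p.is_absolute() else base / p

        outcomes = {
            name: OutcomeSpec(
                data=resolve(spec["path"]),
                n_total=int(spec["n_total"]),
                n_cases=int(spec["n_cases"]),
            )
            for name, spec in raw["outcomes"].items()
        }
        thresholds = Thresholds(**raw.get("thresholds", {}))
        return cls(
            exposure=resolve(raw["exposure"]),
            outcomes=outcomes,
            seed=int(raw["seed"]),
            ld=resolve(raw["ld"]) if raw.get("ld") else None,
            exclusions=resolve(raw["exclusions"]) if raw.get("exclusions") else None,
            thresholds=thresholds,
            methods=tuple(raw.get("methods", DEFAULT_METHODS)),
            n_boot=int(raw.get("n_boot", 1000)),
            n_sim=int(raw.get("n_sim", 1000)),
            alpha=float(raw.get("alpha", 0.05)),
            or_target=float(raw.get("or_target", 1.3)),
            palindromic_mode=str(raw.get("palindromic_mode", "drop")),
            n_outcomes_for_correction=raw.get("n_outcomes_for_correction"),
        )

    def exposure_records(self) -> list[AssociationRecord]:
        if isinstance(self.exposure, (str, Path)):
            return read_gwas_table(self.exposure)
        return list(self.exposure)

    def ld_table(self) -> LDTable | None:
        if self.ld is None:
            return None
        if isinstance(self.ld, LDTable):
            return self.ld
        return LDTable.from_file(self.ld)

    def exclusion_pairs(self) -> list[tuple[str, str]]:
        if self.exclusions is None:
            return []
        if isinstance(self.exclusions, (str, Path)):
            frame = pd.read_csv(self.exclusions, sep="\t", dtype=str)
            cols = list(frame.columns[:2])
            return [(str(a), str(b)) for a, b in frame[cols].itertuples(index=False)]
        return list(self.exclusions)


def classify_evidence(
    pval: float,
    strong_threshold: float = 0.05 / 6,
    suggestive_threshold: float = 0.05,
) -> str:
    """Grade an association as strong / suggestive / none.

    ``strong`` below the multiplicity-corrected threshold, ``suggestive``
    between the corrected and nominal thresholds, ``none`` otherwise.
    """
    if not strong_threshold <= suggestive_threshold:
        raise ValueError("strong_threshold must not exceed suggestive_threshold")
    if pval < strong_threshold:
        return "strong"
    if pval < suggestive_threshold:
        return "suggestive"
    return "none"


def select_instruments(
    exposure: Sequence[AssociationRecord],
    outcome: Sequence[AssociationRecord],
    ld: LDTable | None = None,
    exclusions: Sequence[tuple[str, str]] | None = None,
    thresholds: Thresholds = Thresholds(),
    palindromic_mode: str = "drop",
) -> tuple[list[AssociationRecord], HarmonizedSet, list[Exclusion]]:
    """Run the instrument-selection chain for one outcome.

    Order: significance -> clump -> MAF -> harmonize (with proxy search for
    SNPs missing from the outcome) -> confounder exclusion list -> weak
    (F < f_min) filter.  The returned ledger lists each removed SNP once,
    under the first rule that removed it; retained + removed equals the
    exposure input count.
    """
    ledger: list[Exclusion] = []
    records = significance_filter(list(exposure), thresholds.p_sig, ledger=ledger)
    if ld is not None:
        records = clump(
            records, ld, thresholds.clump_r2, thresholds.clump_window_kb, ledger=ledger
        )
    records = maf_filter(records, thresholds.maf, ledger=ledger)

    outcome = list(outcome)
    outcome_ids = {rec.snp_id for rec in outcome}
    outcome_for_merge = list(outcome)
    if ld is not None:
        for rec in records:
            if rec.snp_id in outcome_ids:
                continue
            proxy = find_proxy(rec.snp_id, outcome, ld, thresholds.proxy_r2)
            if proxy is not None:
                donor = next(o for o in outcome if o.snp_id == proxy)
                outcome_for_merge.append(
                    dataclasses.replace(
                        donor,
                        snp_id=rec.snp_id,
                        annotations={"proxy_for": rec.snp_id, "proxy_snp": proxy},
                    )
                )
                logger.info("using proxy %s for missing SNP %s", proxy, rec.snp_id)

    h = harmonize(records, outcome_for_merge, palindromic_mode=palindromic_mode)
    ledger.extend(h.exclusions)
    retained_ids = set(h.pairs["snp_id"])
    records = [r for r in records if r.snp_id in retained_ids]

    records = apply_exclusion_list(records, list(exclusions or []), ledger=ledger)
    records = weak_instrument_filter(records, thresholds.f_min, ledger=ledger)

    final_ids = {r.snp_id for r in records}
    h = HarmonizedSet(
        h.pairs[h.pairs["snp_id"].isin(final_ids)].reset_index(drop=True), ledger
    )
    for exc in ledger:
        logger.info("excluded %s: %s %s", exc.snp_id, exc.reason.value, exc.note)
    return records, h, ledger


@dataclass
class OutcomeResult:
    outcome: str
    n_candidates: int
    n_snps: int
    instruments: pd.DataFrame  # snp_id, r2_explained, f_stat
    total_r2: float
    ledger: list[Exclusion]
    estimates: list[MREstimate]
    heterogeneity: list  # HeterogeneityResult
    egger_intercept: dict
    presso: object | None
    loo: list
    loo_driven: bool | None
    funnel: pd.DataFrame
    power: float | None
    evidence: str
    error: str | None = None


@dataclass
class AnalysisReport:
    outcomes: dict[str, OutcomeResult]
    config_summary: dict
    version: str = _version

    def to_dict(self) -> dict:
        out: dict = {"version": self.version, "config": self.config_summary, "outcomes": {}}
        for name, res in self.outcomes.items():
            if res.error is not None:
                out["outcomes"][name] = {"error": res.error}
                continue
            out["outcomes"][name] = {
                "n_candidates": res.n_candidates,
                "n_snps": res.n_snps,
                "total_r2": res.total_r2,
                "instruments": res.instruments.to_dict(orient="records"),
                "ledger": [
                    {"snp_id": e.snp_id, "reason": e.reason.value, "note": e.note}
                    for e in res.ledger
                ],
                "estimates": [dataclasses.asdict(e) for e in res.estimates],
                "heterogeneity": [dataclasses.asdict(hh) for hh in res.heterogeneity],
                "egger_intercept": res.egger_intercept,
                "presso": (
                    None
                    if res.presso is None
                    else {
                        "rss_obs": res.presso.rss_obs,
                        "global_pval": res.presso.global_pval,
                        "n_sim": res.presso.n_sim,
                        "outliers": [
                            {"snp_id": s, "pval": p, "flag": f}
                            for s, p, f in zip(
                                res.presso.snp_ids,
                                res.presso.outlier_pvals,
                                res.presso.outlier_flags,
                            )
                        ],
                        "distortion": res.presso.distortion,
                    }
                ),
                "loo": [
                    {"excluded_snp": sid, **dataclasses.asdict(est)}
                    for sid, est in res.loo
                ],
                "loo_driven_by_single_snp": res.loo_driven,
                "funnel": res.funnel.to_dict(orient="records"),
                "power_pct": None if res.power is None else 100.0 * res.power,
                "evidence": res.evidence,
            }
        return out

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    def write(self, out_dir) -> None:
        """Write report.json plus tidy TSV tables under ``out_dir``."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(self.to_json())
        est_frames, het_rows, loo_frames, funnel_frames, ledger_rows, power_rows = (
            [], [], [], [], [], []
        )
        for name, res in self.outcomes.items():
            if res.error is not None:
                continue
            est_frames.append(estimates_table(res.estimates, outcome=name))
            for hh in res.heterogeneity:
                het_rows.append({"outcome": name, **dataclasses.asdict(hh)})
            for sid, est in res.loo:
                loo_frames.append(
                    {"outcome": name, "excluded_snp": sid, "beta": est.beta,
                     "se": est.se, "pval": est.pval}
                )
            f = res.funnel.copy()
            f.insert(0, "outcome", name)
            funnel_frames.append(f)
            for e in res.ledger:
                ledger_rows.append(
                    {"outcome": name, "snp_id": e.snp_id, "reason": e.reason.value,
                     "note": e.note}
                )
            power_rows.append(
                {"outcome": name, "n_snps": res.n_snps, "total_r2": res.total_r2,
                 "power_pct": None if res.power is None else 100.0 * res.power,
                 "evidence": res.evidence}
            )
        if est_frames:
            pd.concat(est_frames).to_csv(out_dir / "estimates.tsv", sep="\t", index=False)
        pd.DataFrame(het_rows).to_csv(out_dir / "heterogeneity.tsv", sep="\t", index=False)
        pd.DataFrame(loo_frames).to_csv(out_dir / "leave_one_out.tsv", sep="\t", index=False)
        if funnel_frames:
            pd.concat(funnel_frames).to_csv(out_dir / "funnel.tsv", sep="\t", index=False)
        pd.DataFrame(ledger_rows).to_csv(out_dir / "ledger.tsv", sep="\t", index=False)
        pd.DataFrame(power_rows).to_csv(out_dir / "power.tsv", sep="\t", index=False)


_ESTIMATOR_DISPATCH = {
    "IVW_FE": lambda h, seed, n_boot: ivw(h, mode="fixed"),
    "IVW_MRE": lambda h, seed, n_boot: ivw(h, mode="mre"),
    "EGGER": lambda h, seed, n_boot: egger(h),
    "WEIGHTED_MEDIAN": lambda h, seed, n_boot: weighted_median(h, n_boot=n_boot, seed=seed),
    "WEIGHTED_MODE": lambda h, seed, n_boot: weighted_mode(h, n_boot=n_boot, seed=seed),
}


def _analyse_outcome(
    name: str,
    cfg: AnalysisConfig,
    exposure: list[AssociationRecord],
    ld: LDTable | None,
    exclusions: list[tuple[str, str]],
    strong_threshold: float,
    seed: int,
) -> OutcomeResult:
    spec = cfg.outcomes[name]
    outcome_records = spec.records()
    records, h, ledger = select_instruments(
        exposure, outcome_records, ld, exclusions, cfg.thresholds, cfg.palindromic_mode
    )
    diags = grade_instruments(records, cfg.thresholds.f_min)
    inst = pd.DataFrame(
        {
            "snp_id": [d.snp_id for d in diags],
            "r2_explained": [d.r2_explained for d in diags],
            "f_stat": [d.f_stat for d in diags],
        }
    )
    total_r2 = float(inst["r2_explained"].sum()) if len(inst) else 0.0

    estimates = []
    for method in cfg.methods:
        if method not in _ESTIMATOR_DISPATCH:
            raise ValueError(f"unknown method {method!r}")
        estimates.append(_ESTIMATOR_DISPATCH[method](h, seed, cfg.n_boot))

    j = h.n_snps
    heterogeneity = []
    if j >= 2:
        heterogeneity.append(cochran_q(h, "IVW"))
    if j >= 3:
        heterogeneity.append(cochran_q(h, "EGGER"))
    egger_intercept: dict = {}
    egger_est = next((e for e in estimates if e.method == "EGGER"), None)
    if egger_est is None and j >= 3:
        egger_est = egger(h)
    if egger_est is not None:
        egger_intercept = {
            "intercept": egger_est.intercept,
            "se": egger_est.intercept_se,
            "pval": egger_est.intercept_pval,
        }
    presso = mr_presso(h, n_sim=cfg.n_sim, seed=seed) if j >= 4 else None
    if j >= 3:
        loo, loo_driven = leave_one_out(h, method="mre", alpha=cfg.alpha)
    else:
        loo, loo_driven = [], None
    funnel = funnel_data(h) if j >= 1 else pd.DataFrame(columns=["snp_id", "ratio", "precision"])

    power = None
    if 0.0 < total_r2 < 1.0:
        power = mr_power_binary(
            PowerQuery(
                n_total=spec.n_total, n_cases=spec.n_cases, r2_xz=total_r2,
                or_target=cfg.or_target, alpha=cfg.alpha, label=name,
            )
        )
    primary = next(
        (e for e in estimates if e.method == "IVW_FE"), estimates[0] if estimates else None
    )
    evidence = (
        classify_evidence(primary.pval, strong_threshold, cfg.alpha) if primary else "none"
    )
    return OutcomeResult(
        outcome=name,
        n_candidates=len(exposure),
        n_snps=j,
        instruments=inst,
        total_r2=total_r2,
        ledger=ledger,
        estimates=estimates,
        heterogeneity=heterogeneity,
        egger_intercept=egger_intercept,
        presso=presso,
        loo=loo,
        loo_driven=loo_driven,
        funnel=funnel,
        power=power,
        evidence=evidence,
    )


def run_analysis(cfg: AnalysisConfig) -> AnalysisReport:
    """Run the full per-outcome workflow; one outcome failing does not stop
    the others (its error is recorded in the report)."""
    exposure = cfg.exposure_records()
    ld = cfg.ld_table()
    exclusions = cfg.exclusion_pairs()
    n_corr = cfg.n_outcomes_for_correction or len(cfg.outcomes)
    strong_threshold = cfg.alpha / n_corr

    # one independent, reproducible seed stream per outcome
    names = list(cfg.outcomes)
    children = np.random.SeedSequence(cfg.seed).spawn(len(names))
    results: dict[str, OutcomeResult] = {}
    for name, ss in zip(names, children):
        seed = int(ss.generate_state(1)[0] % (2**31))
        try:
            results[name] = _analyse_outcome(
                name, cfg, exposure, ld, exclusions, strong_threshold, seed
            )
        except Exception as exc:  # noqa: BLE001 - report and continue
            logger.error("outcome %s failed: %s", name, exc)
            results[name] = OutcomeResult(
                outcome=name, n_candidates=len(exposure), n_snps=0,
                instruments=pd.DataFrame(), total_r2=0.0, ledger=[], estimates=[],
                heterogeneity=[], egger_intercept={}, presso=None, loo=[],
                loo_driven=None, funnel=pd.DataFrame(), power=None,
                evidence="none", error=f"{type(exc).__name__}: {exc}",
            )
    config_summary = {
        "seed": cfg.seed,
        "alpha": cfg.alpha,
        "strong_threshold": strong_threshold,
        "methods": list(cfg.methods),
        "thresholds": dataclasses.asdict(cfg.thresholds),
        "n_boot": cfg.n_boot,
        "n_sim": cfg.n_sim,
        "or_target": cfg.or_target,
        "palindromic_mode": cfg.palindromic_mode,
        "n_outcomes": len(cfg.outcomes),
    }
    return AnalysisReport(outcomes=results, config_summary=config_summary)


def run_bidirectional(
    cfg_forward: AnalysisConfig, cfg_reverse: AnalysisConfig
) -> tuple[AnalysisReport, AnalysisReport]:
    """Forward and reverse-direction reports from the same pipeline.

    The reverse config swaps exposure and outcome roles; its instruments are
    selected from the reverse exposure (the forward outcome trait), never
    reused from the forward run.
    """
    return run_analysis(cfg_forward), run_analysis(cfg_reverse)
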