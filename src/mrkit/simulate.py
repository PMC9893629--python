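"""Synthetic GWAS summary statistics with known ground truth.

The generator emulates the statistical structure a two-sample MR analysis
assumes: per-SNP exposure effects gamma_j with sampling noise, outcome
effects Gamma_j = beta * gamma_j + alpha_j + noise where alpha_j is a
configurable horizontal-pleiotropy term (none / balanced / directional /
InSIDE-violating), allele pairs including palindromic and strand-flipped
cases, realistic allele frequencies, and block LD structure for clumping
tests.  Standard errors follow the 1/sqrt(2 N EAF(1-EAF)) scaling so the
R^2 and F instrument-strength formulas behave realistically.

Defaults mirror the ankylosing-spondylitis-on-stroke setting the package
was exercised against: exposure GWAS of 166,144 Europeans (1,462 cases),
outcome GWAS of 446,696 (40,585 cases), and a causal effect of 0.05 on the
log-odds scale (OR about 1.05).

Also provides two concrete instrument fixtures: the seven published FinnGen
ankylosing-spondylitis instruments, and a 13-candidate selection scenario
exercising every exclusion rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .instruments import LDTable
from .summary_io import AssociationRecord, complement_allele

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_summary_stats",
    "simulate_ld_table",
    "finngen_as_instruments",
    "selection_scenario",
    "truth_frame",
]

GENOME_WIDE_P = 5e-8
_NONPALINDROMIC_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass(frozen=True)
class SimulationConfig:
    """Stated world for one simulated exposure/outcome dataset pair."""

    seed: int
    n_snps: int = 50
    beta_causal: float = 0.05
    pleiotropy_mode: str = "none"  # none | balanced | directional | inside_violating
    pleiotropy_sd: float = 0.01
    pleiotropy_mean: float = 0.02  # directional mode only
    invalid_fraction: float = 0.0
    gamma_sd: float = 0.1
    n_exposure: int = 166_144
    n_cases_exposure: int = 1_462
    n_outcome: int = 446_696
    n_cases_outcome: int = 40_585
    maf_range: tuple[float, float] = (0.05, 0.5)
    palindromic_fraction: float = 0.0
    strand_flip_fraction: float = 0.0
    ld_blocks: tuple[tuple[int, float], ...] | None = None

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if self.pleiotropy_mode not in ("none", "balanced", "directional", "inside_violating"):
            raise ValueError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        for name in ("invalid_fraction", "palindromic_fraction", "strand_flip_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must sit inside (0, 0.5], got {self.maf_range}")
        if self.gamma_sd <= 0:
            raise ValueError("gamma_sd must be positive")
        for name in ("n_exposure", "n_outcome"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be >= 2")


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth behind one simulated dataset pair."""

    snp_ids: list[str]
    gamma_true: np.ndarray
    alpha: np.ndarray
    valid: np.ndarray  # False where alpha was injected
    beta_causal: float


def truth_frame(truth: SimulationTruth) -> pd.DataFrame:
    """Sidecar table of the per-SNP ground truth."""
    return pd.DataFrame(
        {
            "snp_id": truth.snp_ids,
            "gamma_true": truth.gamma_true,
            "alpha": truth.alpha,
            "valid": truth.valid,
            "beta_causal": truth.beta_causal,
        }
    )


def _draw_significant_gamma(rng, se, gamma_sd):
    """True exposure effects, resampled until genome-wide significant.

    Mimics a post-selection instrument set: every instrument's true effect
    is large enough that its expected test statistic clears p < 5e-8.
    """
    z_min = stats.norm.isf(GENOME_WIDE_P / 2.0)
    gamma = rng.normal(0.0, gamma_sd, size=se.size)
    for _ in range(10_000):
        weak = np.abs(gamma) / se < z_min
        if not weak.any():
            return gamma
        gamma[weak] = rng.normal(0.0, gamma_sd, size=int(weak.sum()))
    raise RuntimeError(
        "could not draw genome-wide-significant effects; increase gamma_sd "
        "or the exposure sample size"
    )


def _two_sided_p(beta, se):
    p = 2.0 * stats.norm.sf(np.abs(beta) / se)
    return np.clip(p, 1e-300, 1.0)


def simulate_summary_stats(
    cfg: SimulationConfig,
) -> tuple[list[AssociationRecord], list[AssociationRecord], SimulationTruth]:
    """Generate an (exposure records, outcome records, truth) triple.

    All randomness flows from ``cfg.seed``; identical configs give
    bit-identical output.  Pleiotropy is applied on the exposure-raising
    orientation (the injected effect is multiplied by sign(gamma_j)), so a
    directional mean is directional in the sense MR-Egger estimates it.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    j = cfg.n_snps
    snp_ids = [f"rs{1_000_001 + i}" for i in range(j)]

    lo, hi = cfg.maf_range
    maf = rng.uniform(lo, hi, size=j)
    eaf = np.where(rng.random(j) < 0.5, maf, 1.0 - maf)

    se_gamma = 1.0 / np.sqrt(2.0 * cfg.n_exposure * eaf * (1.0 - eaf))
    se_Gamma = 1.0 / np.sqrt(2.0 * cfg.n_outcome * eaf * (1.0 - eaf))

    gamma_true = _draw_significant_gamma(rng, se_gamma, cfg.gamma_sd)
    gamma_obs = rng.normal(gamma_true, se_gamma)

    alpha = np.zeros(j)
    valid = np.ones(j, dtype=bool)
    if cfg.pleiotropy_mode != "none" and cfg.invalid_fraction > 0.0:
        n_invalid = int(round(cfg.invalid_fraction * j))
        idx = rng.choice(j, size=n_invalid, replace=False)
        sign = np.sign(gamma_true[idx])
        sign[sign == 0] = 1.0
        if cfg.pleiotropy_mode == "balanced":
            alpha[idx] = sign * rng.normal(0.0, cfg.pleiotropy_sd, size=n_invalid)
        elif cfg.pleiotropy_mode == "directional":
            alpha[idx] = sign * rng.normal(cfg.pleiotropy_mean, cfg.pleiotropy_sd, size=n_invalid)
        else:  # inside_violating: direct effect correlated with instrument strength
            alpha[idx] = 0.5 * gamma_true[idx] + rng.normal(0.0, cfg.pleiotropy_sd, size=n_invalid)
        valid[idx] = False

    Gamma_true = cfg.beta_causal * gamma_true + alpha
    Gamma_obs = rng.normal(Gamma_true, se_Gamma)

    # allele assignment
    pal = rng.random(j) < cfg.palindromic_fraction
    flip = rng.random(j) < cfg.strand_flip_fraction
    pal_choice = rng.integers(0, len(_PALINDROMIC_PAIRS), size=j)
    non_choice = rng.integers(0, len(_NONPALINDROMIC_PAIRS), size=j)

    if cfg.ld_blocks:
        _, positions = simulate_ld_table(cfg)
    else:
        positions = {sid: ("1", 1_000_000 * (i + 1)) for i, sid in enumerate(snp_ids)}

    p_exp = _two_sided_p(gamma_obs, se_gamma)
    p_out = _two_sided_p(Gamma_obs, se_Gamma)

    exposure: list[AssociationRecord] = []
    outcome: list[AssociationRecord] = []
    for i, sid in enumerate(snp_ids):
        if pal[i]:
            ea, oa = _PALINDROMIC_PAIRS[pal_choice[i]]
        else:
            ea, oa = _NONPALINDROMIC_PAIRS[non_choice[i]]
        chrom, pos = positions.get(sid, ("1", 1_000_000 * (i + 1)))
        exposure.append(
            AssociationRecord(
                snp_id=sid, effect_allele=ea, other_allele=oa, eaf=float(eaf[i]),
                beta=float(gamma_obs[i]), se=float(se_gamma[i]), pval=float(p_exp[i]),
                n=cfg.n_exposure, n_cases=cfg.n_cases_exposure, chrom=chrom, pos=pos,
            )
        )
        oea, ooa = ea, oa
        if flip[i]:
            oea, ooa = complement_allele(ea), complement_allele(oa)
        outcome.append(
            AssociationRecord(
                snp_id=sid, effect_allele=oea, other_allele=ooa, eaf=float(eaf[i]),
                beta=float(Gamma_obs[i]), se=float(se_Gamma[i]), pval=float(p_out[i]),
                n=cfg.n_outcome, n_cases=cfg.n_cases_outcome, chrom=chrom, pos=pos,
            )
        )
    truth = SimulationTruth(
        snp_ids=snp_ids,
        gamma_true=gamma_true,
        alpha=alpha,
        valid=valid,
        beta_causal=cfg.beta_causal,
    )
    return exposure, outcome, truth


def simulate_ld_table(cfg: SimulationConfig) -> tuple[LDTable, dict[str, tuple[str, int]]]:
    """Block-diagonal LD for the first sum(block sizes) simulated SNP ids.

    SNPs take consecutive positions 1 kb apart on one chromosome; pairs
    within a block share the block's r2, across-block pairs are absent
    (r2 = 0).  Returns the table and a snp_id -> (chrom, pos) map.
    """
    if not cfg.ld_blocks:
        raise ValueError("ld_blocks must be non-empty")
    table = LDTable()
    positions: dict[str, tuple[str, int]] = {}
    idx = 0
    for size, r2 in cfg.ld_blocks:
        members = []
        for _ in range(size):
            sid = f"rs{1_000_001 + idx}"
            positions[sid] = ("1", 1000 * (idx + 1))
            members.append(sid)
            idx += 1
        for a_i in range(len(members)):
            for b_i in range(a_i + 1, len(members)):
                table.set(members[a_i], members[b_i], r2)
    return table, positions


# ---------------------------------------------------------------------------
# Published-instrument fixtures
# ---------------------------------------------------------------------------

_AS_EXPOSURE_N = 166_144  # 1,462 ankylosing-spondylitis cases + 164,682 controls
_AS_EXPOSURE_CASES = 1_462

# The seven published FinnGen ankylosing-spondylitis instruments:
# (snp, gene, chrom, EA, NEA, EAF, beta, se, p, variance_pct, f_published)
_AS_INSTRUMENTS = [
    ("rs13033284", "RP11-642D6.1", "2", "C", "T", 0.6277, -0.2214, 0.0386, 9.67008e-09, 0.4023, 671.2),
    ("rs9264277", "TBC1D22B", "6", "C", "T", 0.7297, 0.5198, 0.0448, 3.73164e-31, 0.2990, 498.2),
    ("rs34982906", "ZFP57", "6", "C", "T", 0.05278, 0.8211, 0.0918, 3.82296e-19, 0.0714, 118.7),
    ("rs9391773", None, "6", "T", "G", 0.1285, 2.6349, 0.0702, 1e-200, 0.1220, 202.9),
    ("rs79693223", "TBC1D22B", "6", "T", "C", 0.04504, 1.2953, 0.1062, 3.36279e-34, 0.0533, 88.7),
    ("rs76644067", "CLPSL2", "6", "A", "G", 0.04745, 0.7328, 0.0946, 9.44061e-15, 0.0672, 111.7),
    ("rs10807943", "SLC29A4", "7", "C", "T", 0.9365, -0.5628, 0.0812, 4.09826e-12, 0.0912, 151.7),
]


def finngen_as_instruments() -> list[AssociationRecord]:
    """The seven published FinnGen ankylosing-spondylitis instruments.

    Each record carries the published per-SNP variance explained (percent)
    and F statistic in ``annotations`` (keys ``variance_pct``, ``f_published``,
    ``gene``); positions are not published, so ``pos`` is None and the
    records are ineligible for clumping.
    """
    records = []
    for sid, gene, ch, ea, nea, eaf, beta, se, p, var_pct, f_pub in _AS_INSTRUMENTS:
        rec = AssociationRecord(
            snp_id=sid, effect_allele=ea, other_allele=nea, eaf=eaf, beta=beta,
            se=se, pval=p, n=_AS_EXPOSURE_N, n_cases=_AS_EXPOSURE_CASES, chrom=ch,
            annotations={"gene": gene, "variance_pct": var_pct, "f_published": f_pub},
        )
        rec.validate()
        records.append(rec)
    return records


def selection_scenario(
    seed: int = 0,
) -> tuple[list[AssociationRecord], list[AssociationRecord], list[tuple[str, str]]]:
    """Synthetic 13-candidate instrument-selection scenario.

    Thirteen genome-wide-significant exposure candidates of which exactly six
    fall to the documented exclusion rules: rs181316459 is absent from the
    outcome with no proxy, rs16894011 is palindromic, rs9265893 has
    incompatible alleles, and rs62394289 / rs9378220 / rs112733823 sit on
    the confounder exclusion list (blood-pressure and rheumatoid-arthritis
    associations).  The seven survivors are the published
    ankylosing-spondylitis instruments.

    The six extra candidates and all outcome-side associations are SYNTHETIC
    stand-ins (only the rsIDs, allele pathologies and exclusion reasons are
    real); outcome effects are drawn around a causal effect of 0.05.

    Returns (exposure records, outcome records, confounder exclusion list).
    """
    rng = np.random.default_rng(seed)
    exposure = list(finngen_as_instruments())

    def synth(sid, ea, nea, eaf, beta):
        se = 0.08
        return AssociationRecord(
            snp_id=sid, effect_allele=ea, other_allele=nea, eaf=eaf, beta=beta,
            se=se, pval=float(_two_sided_p(np.array([beta]), np.array([se]))[0]),
            n=_AS_EXPOSURE_N, n_cases=_AS_EXPOSURE_CASES, chrom="6",
        )

    exposure += [
        synth("rs181316459", "C", "T", 0.030, 1.10),
        synth("rs16894011", "A", "T", 0.250, 0.62),
        synth("rs9265893", "C", "T", 0.180, -0.71),
        synth("rs62394289", "A", "G", 0.120, 0.66),
        synth("rs9378220", "T", "C", 0.310, -0.58),
        synth("rs112733823", "G", "A", 0.090, 0.74),
    ]

    n_out, cases_out = 446_696, 40_585
    outcome: list[AssociationRecord] = []
    for rec in exposure:
        if rec.snp_id == "rs181316459":
            continue  # absent from the outcome, and no proxy exists
        ea, nea = rec.effect_allele, rec.other_allele
        if rec.snp_id == "rs9265893":
            nea = "G"  # irreconcilable with the exposure's C/T
        se_out = 1.0 / np.sqrt(2.0 * n_out * rec.eaf * (1.0 - rec.eaf))
        beta_out = float(rng.normal(0.05 * rec.beta, se_out))
        outcome.append(
            AssociationRecord(
                snp_id=rec.snp_id, effect_allele=ea, other_allele=nea, eaf=rec.eaf,
                beta=beta_out, se=float(se_out),
                pval=float(_two_sided_p(np.array([beta_out]), np.array([se_out]))[0]),
                n=n_out, n_cases=cases_out, chrom=rec.chrom,
            )
        )
    exclusion_list = [
        ("rs62394289", "associated with high blood pressure (SLC17A3)"),
        ("rs9378220", "associated with high blood pressure (TRIM31)"),
        ("rs112733823", "associated with rheumatoid arthritis (LINC00243)"),
    ]
    return exposure, outcome, exclusion_list
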