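r"""Synthetic GWAS summary statistics under a known causal chain.

Generates per-variant association statistics for an exposure, a mediator and
a binary outcome (log-odds scale) linked by

    exposure --beta1--> mediator --beta2--> outcome
        \___________beta_direct___________/

so that every estimator in the package can be checked against known truth.
Simulation is at the summary level: per-SNP instrument strengths are drawn,
and the three observed effect columns add independent Gaussian sampling noise
at the configured standard errors.  Horizontal pleiotropy enters as an
additive per-SNP offset on the outcome effects of the exposure instruments.
LD is emulated by near-duplicate records with correlated noise, shipped with
an explicit r-squared matrix.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

SUMMARY_COLUMNS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n",
]

_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
_NON_PALINDROMIC_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]


@dataclass(frozen=True)
class SimScenario:
    """Generative parameters for the synthetic causal chain.

    Defaults emulate the study conditions: an immune-trait exposure
    (GWAS n ~ 3,757), a plasma-protein mediator (n ~ 35,559) and a binary
    outcome analysed on the log-odds scale in a large biobank cohort
    (2,843 cases / 389,580 controls).  Instrument strengths are drawn so the
    single-SNP F-statistic is comfortably above the conventional weak-
    instrument cutoff of 10.
    """

    n_snps_exposure: int = 30
    n_snps_mediator: int = 30
    beta1_true: float = -0.3          # exposure -> mediator, SD per SD
    beta2_true: float = -0.6          # mediator -> outcome, log-odds per SD
    beta_direct_true: float = 0.2     # direct exposure -> outcome, log-odds per SD
    gamma_mean: float = 0.25          # mean per-SNP instrument strength
    gamma_sd: float = 0.05
    se_exposure: float = 0.03
    se_mediator: float = 0.03
    se_outcome: float = 0.03
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    frac_palindromic: float = 0.0
    ld_block_spec: tuple[tuple[int, float], ...] = ()
    n_exposure: int = 3757
    n_mediator: int = 35559
    n_outcome: int = 392423
    seed: int = 0

    @property
    def total_effect_true(self) -> float:
        return self.beta_direct_true + self.beta1_true * self.beta2_true

    def __post_init__(self) -> None:
        for name in ("se_exposure", "se_mediator", "se_outcome"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")
        if not 0.0 <= self.frac_palindromic <= 1.0:
            raise ValueError("frac_palindromic must lie in [0, 1]")
        for size, r2 in self.ld_block_spec:
            if size < 2:
                raise ValueError("LD block size must be >= 2")
            if not 0.0 <= r2 <= 1.0:
                raise ValueError("LD r2 must lie in [0, 1]")
        if self.n_snps_exposure < 1 or self.n_snps_mediator < 0:
            raise ValueError("need at least one exposure SNP")


@dataclass
class TripleGWAS:
    """Summary statistics for the three traits plus the generating truth.

    ``mediator_instrument_ids`` lists the mediator's own loci (the analogue
    of cis protein-QTLs), as opposed to exposure loci whose mediator
    association is transmitted through the causal chain."""

    exposure_stats: pd.DataFrame
    mediator_stats: pd.DataFrame
    outcome_stats: pd.DataFrame
    ld_matrix: pd.DataFrame
    truth: SimScenario
    mediator_instrument_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        ids = set(self.exposure_stats["variant_id"])
        assert ids == set(self.mediator_stats["variant_id"])
        assert ids == set(self.outcome_stats["variant_id"])


def _pvalue(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    z = np.abs(beta / se)
    # sf keeps precision for genome-wide-significant z scores
    return np.clip(2.0 * stats.norm.sf(z), np.finfo(float).tiny, 1.0)


def _assign_alleles(rng: np.random.Generator, n: int, frac_palindromic: float):
    is_pal = rng.random(n) < frac_palindromic
    ea = np.empty(n, dtype=object)
    oa = np.empty(n, dtype=object)
    pal_idx = rng.integers(0, len(_PALINDROMIC_PAIRS), size=n)
    non_idx = rng.integers(0, len(_NON_PALINDROMIC_PAIRS), size=n)
    for i in range(n):
        ea[i], oa[i] = (
            _PALINDROMIC_PAIRS[pal_idx[i]] if is_pal[i]
            else _NON_PALINDROMIC_PAIRS[non_idx[i]]
        )
    return ea, oa


def simulate_summary_stats(scenario: SimScenario) -> TripleGWAS:
    """Draw one realisation of the causal-chain summary statistics.

    Exposure instruments carry the chain: their mediator effects are
    ``beta1 * gamma`` and their outcome effects
    ``(beta_direct + beta1*beta2) * gamma`` plus a per-SNP pleiotropic offset.
    Mediator instruments are independent of the exposure (effects ~ 0 there)
    and hit the outcome through ``beta2`` only, which is what the second leg
    of two-step mediation MR estimates.
    """
    sc = scenario
    rng = np.random.default_rng(sc.seed)

    n_exp = sc.n_snps_exposure
    n_med = sc.n_snps_mediator
    n_tot = n_exp + n_med

    gamma = rng.normal(sc.gamma_mean, sc.gamma_sd, size=n_exp)   # exposure IVs
    delta = rng.normal(sc.gamma_mean, sc.gamma_sd, size=n_med)   # mediator IVs
    alpha = (
        rng.normal(sc.pleiotropy_mean, sc.pleiotropy_sd, size=n_exp)
        if sc.pleiotropy_sd > 0 or sc.pleiotropy_mean != 0.0
        else np.zeros(n_exp)
    )

    # true per-SNP effects on each trait, exposure SNPs first
    true_exp = np.concatenate([gamma, np.zeros(n_med)])
    true_med = np.concatenate([sc.beta1_true * gamma, delta])
    true_out = np.concatenate([
        sc.total_effect_true * gamma + alpha,
        sc.beta2_true * delta,
    ])

    noise_exp = rng.normal(0.0, 1.0, size=n_tot)
    noise_med = rng.normal(0.0, 1.0, size=n_tot)
    noise_out = rng.normal(0.0, 1.0, size=n_tot)

    variant_id = np.array([f"rs{i + 1:06d}" for i in range(n_tot)], dtype=object)
    chrom = np.array([str(1 + i % 22) for i in range(n_tot)], dtype=object)
    pos = 1_000_000 + 2_000_000 * np.arange(n_tot)
    ea, oa = _assign_alleles(rng, n_tot, sc.frac_palindromic)
    eaf = rng.uniform(0.10, 0.90, size=n_tot)

    # LD blocks: append near-duplicates of the first exposure SNPs, with
    # effect noise correlated at r and true effects scaled by r (so the
    # marginal effect of a tag SNP is attenuated by its LD with the lead).
    ld_pairs: list[tuple[str, str, float]] = []
    extra_rows: dict[str, list] = {k: [] for k in (
        "variant_id", "chrom", "pos", "ea", "oa", "eaf",
        "true_exp", "true_med", "true_out",
        "noise_exp", "noise_med", "noise_out",
    )}
    lead_cursor = 0
    dup_counter = 0
    for size, r2 in sc.ld_block_spec:
        if lead_cursor >= n_tot:
            break
        lead = lead_cursor
        lead_cursor += 1
        r = float(np.sqrt(r2))
        for _ in range(size - 1):
            dup_counter += 1
            vid = f"rs{n_tot + dup_counter:06d}"
            ld_pairs.append((variant_id[lead], vid, r2))
            extra_rows["variant_id"].append(vid)
            extra_rows["chrom"].append(chrom[lead])
            extra_rows["pos"].append(int(pos[lead]) + 5_000 * dup_counter)
            extra_rows["ea"].append(ea[lead])
            extra_rows["oa"].append(oa[lead])
            extra_rows["eaf"].append(eaf[lead])
            extra_rows["true_exp"].append(r * true_exp[lead])
            extra_rows["true_med"].append(r * true_med[lead])
            extra_rows["true_out"].append(r * true_out[lead])
            w = np.sqrt(max(0.0, 1.0 - r2))
            extra_rows["noise_exp"].append(r * noise_exp[lead] + w * rng.normal())
            extra_rows["noise_med"].append(r * noise_med[lead] + w * rng.normal())
            extra_rows["noise_out"].append(r * noise_out[lead] + w * rng.normal())

    if dup_counter:
        variant_id = np.concatenate([variant_id, extra_rows["variant_id"]])
        chrom = np.concatenate([chrom, extra_rows["chrom"]])
        pos = np.concatenate([pos, extra_rows["pos"]])
        ea = np.concatenate([ea, extra_rows["ea"]])
        oa = np.concatenate([oa, extra_rows["oa"]])
        eaf = np.concatenate([eaf, extra_rows["eaf"]])
        true_exp = np.concatenate([true_exp, extra_rows["true_exp"]])
        true_med = np.concatenate([true_med, extra_rows["true_med"]])
        true_out = np.concatenate([true_out, extra_rows["true_out"]])
        noise_exp = np.concatenate([noise_exp, extra_rows["noise_exp"]])
        noise_med = np.concatenate([noise_med, extra_rows["noise_med"]])
        noise_out = np.concatenate([noise_out, extra_rows["noise_out"]])

    def _frame(true_beta, noise, se, n_samples):
        beta = true_beta + se * noise
        se_arr = np.full(beta.shape, float(se))
        return pd.DataFrame({
            "variant_id": variant_id,
            "chrom": chrom,
            "pos": pos.astype(int),
            "effect_allele": ea,
            "other_allele": oa,
            "eaf": np.round(eaf, 6),
            "beta": beta,
            "se": se_arr,
            "pval": _pvalue(beta, se_arr),
            "n": n_samples,
        })

    exposure = _frame(true_exp, noise_exp, sc.se_exposure, sc.n_exposure)
    mediator = _frame(true_med, noise_med, sc.se_mediator, sc.n_mediator)
    outcome = _frame(true_out, noise_out, sc.se_outcome, sc.n_outcome)

    k = len(variant_id)
    ld = pd.DataFrame(np.eye(k), index=variant_id, columns=variant_id)
    for a, b, r2 in ld_pairs:
        ld.loc[a, b] = r2
        ld.loc[b, a] = r2

    mediator_ids = tuple(variant_id[n_exp:n_tot])
    return TripleGWAS(exposure, mediator, outcome, ld, sc, mediator_ids)


def write_fixture(triple: TripleGWAS, path: str | Path) -> dict[str, Path]:
    """Write the three summary-stat tables, the LD matrix and a truth sidecar.

    Files are plain TSV (round-trippable by :func:`twostepmr.io
    .read_summary_stats`) plus a YAML sidecar holding the generating
    scenario.  Output is byte-identical for a fixed scenario seed.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    paths = {
        "exposure": path / "exposure.tsv",
        "mediator": path / "mediator.tsv",
        "outcome": path / "outcome.tsv",
        "ld": path / "ld.tsv",
        "truth": path / "truth.yaml",
    }
    frames = {
        "exposure": triple.exposure_stats,
        "mediator": triple.mediator_stats,
        "outcome": triple.outcome_stats,
    }
    for key, df in frames.items():
        df.to_csv(paths[key], sep="\t", index=False, float_format="%.10g")
    triple.ld_matrix.to_csv(paths["ld"], sep="\t", index_label="variant_id",
                            float_format="%.10g")
    truth = dataclasses.asdict(triple.truth)
    truth["ld_block_spec"] = [list(b) for b in triple.truth.ld_block_spec]
    with open(paths["truth"], "w") as fh:
        yaml.safe_dump(truth, fh, sort_keys=True)
    return paths


def simulate_screen_panel(
    n_exposures: int,
    causal_indices: tuple[int, ...] = (),
    seed: int = 0,
    causal_kw: dict | None = None,
    null_kw: dict | None = None,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame, pd.DataFrame]:
    """Simulate an exposure panel sharing one outcome, for screen tests.

    Each exposure gets its own variant namespace (ids prefixed ``e<k>_``);
    the outcome file is the concatenation of the per-exposure outcome
    records, emulating one outcome GWAS covering every instrument.  Causal
    exposures use the default chain scenario, null exposures a
    beta1=beta2=beta_direct=0 scenario; both overridable.

    Returns (exposure stats by trait id, outcome stats, LD r2 matrix).
    """
    seeds = np.random.SeedSequence(seed).generate_state(n_exposures) % (2**31)
    exposures: dict[str, pd.DataFrame] = {}
    outcome_parts = []
    ld_parts = []
    for k in range(n_exposures):
        kw = dict(causal_kw or {}) if k in causal_indices else dict(
            null_kw or dict(beta1_true=0.0, beta2_true=0.0,
                            beta_direct_true=0.0))
        kw["seed"] = int(seeds[k])
        triple = simulate_summary_stats(SimScenario(**kw))
        prefix = f"e{k}_"
        exp = triple.exposure_stats.copy()
        out = triple.outcome_stats.copy()
        exp["variant_id"] = prefix + exp["variant_id"]
        out["variant_id"] = prefix + out["variant_id"]
        trait = f"exposure_{k:02d}"
        exposures[trait] = exp
        outcome_parts.append(out)
        ld = triple.ld_matrix.copy()
        ld.index = prefix + ld.index
        ld.columns = prefix + ld.columns
        ld_parts.append(ld)

    outcome = pd.concat(outcome_parts, ignore_index=True)
    all_ids = np.concatenate([ld.index.to_numpy() for ld in ld_parts])
    ld_full = pd.DataFrame(np.eye(len(all_ids)), index=all_ids,
                           columns=all_ids)
    for ld in ld_parts:
        ld_full.loc[ld.index, ld.columns] = ld.to_numpy()
    return exposures, outcome, ld_full


def read_truth(path: str | Path) -> SimScenario:
    """Load a truth sidecar written by :func:`write_fixture`."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    raw["ld_block_spec"] = tuple(tuple(b) for b in raw.get("ld_block_spec", []))
    return SimScenario(**raw)
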