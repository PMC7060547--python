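"""Relative-abundance estimators, biomass arithmetic and accuracy metrics.

Besides the signature-based ratios (the method of interest), the module
implements the comparison estimators computed on the same data — raw total
TSM shares, specific-peptide shares, and the two-unique-peptide spectral
count estimator — plus the community-standard bookkeeping that turns genomic
DNA fractions and cell volumes into expected cell-count and biomass ratios.
"""

from __future__ import annotations

from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from phylopep.signature import SignatureMixtureResults
from phylopep.tsm import TsmTable, ASSIGNED_RANK


def _shares(values: np.ndarray, what: str) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if np.any(values < 0):
        raise ValueError(f"{what} must be non-negative")
    total = values.sum()
    if total <= 0:
        raise ValueError(f"all {what} are zero")
    return 100.0 * values / total


def relative_ratios(fit: SignatureMixtureResults | Sequence[float]
                    ) -> np.ndarray:
    """Percent contribution of each reference: 100 * N_k / sum N_j."""
    if isinstance(fit, SignatureMixtureResults):
        n = fit.abundances.to_numpy()
    else:
        n = np.asarray(fit, dtype=float)
    return _shares(n, "fitted abundances")


def total_tsm_ratio(table: TsmTable, refs: Sequence,
                    rank: str = ASSIGNED_RANK) -> np.ndarray:
    """Share of raw TSM counts over the references (biased by shared
    peptides; provided for comparison)."""
    counts = np.array([table.tsm(rank, r) for r in refs], dtype=float)
    return _shares(counts, "TSM counts")


def specific_peptide_ratio(table: TsmTable, refs: Sequence, rank: str
                           ) -> np.ndarray:
    """Share of rank-level specific peptide counts over the references."""
    counts = np.array(
        [float(table.counts(rank, r)["specific_peptides"]) for r in refs])
    if counts.sum() <= 0:
        raise ValueError(
            "no specific peptides at this rank for any reference; "
            "try a higher (less resolved) rank")
    return _shares(counts, "specific peptide counts")


def two_unique_peptide_estimator(proteins: pd.DataFrame, refs: Sequence,
                                 min_unique: int = 2) -> np.ndarray:
    """Protein-centric comparison estimator.

    `proteins` columns: taxon, spectral_count, unique_peptides.  Per
    reference, spectral counts of proteins with at least `min_unique` unique
    peptides are summed, then normalised across references.
    """
    qual = proteins[proteins["unique_peptides"] >= min_unique]
    if qual.empty:
        raise ValueError("no protein has enough unique peptides")
    counts = np.array([
        float(qual.loc[qual["taxon"] == r, "spectral_count"].sum())
        for r in refs
    ])
    if counts.sum() <= 0:
        raise ValueError("no qualifying protein for any reference")
    return _shares(counts, "spectral counts")


def mape(estimated: Sequence[float], expected: Sequence[float]) -> float:
    """Mean absolute error in percentage points across samples."""
    est = np.asarray(estimated, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if est.shape != exp.shape:
        raise ValueError("estimated and expected lengths differ")
    return float(np.mean(np.abs(est - exp)))


class LinearityResult(NamedTuple):
    r_squared: float            # OLS of estimated on expected
    slope: float
    intercept: float
    r_squared_identity: float   # 1 - SS(est - exp) / SS(exp - mean)


def linearity(estimated: Sequence[float], expected: Sequence[float]
              ) -> LinearityResult:
    """Linear-response diagnostics of an estimator against the design."""
    est = np.asarray(estimated, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if est.shape != exp.shape or est.size < 3:
        raise ValueError("need at least 3 paired points")
    if np.ptp(exp) == 0:
        raise ValueError("expected values are constant; regression undefined")
    fit = stats.linregress(exp, est)
    ss_tot = float(np.sum((est - est.mean()) ** 2))
    ss_id = float(np.sum((est - exp) ** 2))
    r2_id = 1.0 - ss_id / ss_tot if ss_tot > 0 else float("nan")
    return LinearityResult(float(fit.rvalue ** 2), float(fit.slope),
                           float(fit.intercept), r2_id)


# -- community-standard biomass arithmetic ---------------------------------

def cell_count_ratios(dna_percent: Sequence[float],
                      genome_size_mb: Sequence[float]) -> np.ndarray:
    """Expected cell-count shares assuming one genome copy per cell.

    r_i = 100 * (dna_i / size_i) / sum_j (dna_j / size_j).
    """
    dna = np.asarray(dna_percent, dtype=float)
    size = np.asarray(genome_size_mb, dtype=float)
    if np.any(size <= 0):
        raise ValueError("genome sizes must be positive")
    return _shares(dna / size, "genome-copy counts")


def volume_proxy_biomass(cell_count_ratio: Sequence[float],
                         volume_um3: Sequence[float],
                         normalize: bool = False) -> np.ndarray:
    """Cell-count share times cell volume as a rough biomass proxy.

    Reported unnormalised by default (the natural product scale does not sum
    to 100); ``normalize=True`` rescales the vector to sum to 100.
    """
    r = np.asarray(cell_count_ratio, dtype=float)
    v = np.asarray(volume_um3, dtype=float)
    if np.any(v < 0):
        raise ValueError("volumes must be non-negative")
    prod = r * v
    return _shares(prod, "volume products") if normalize else prod


def signature_biomass_shares(signature_tsms: Sequence[float]) -> np.ndarray:
    """Relative biomass in percent from signature-fitted TSM quantities."""
    return _shares(np.asarray(signature_tsms, dtype=float),
                   "signature TSM quantities")


def biomass_table(meta: pd.DataFrame, normalize_volume: bool = False
                  ) -> pd.DataFrame:
    """Community-standard report table.

    `meta` columns: species, dna_percent, genome_mb, volume_um3,
    signature_tsm.  Adds derived cell-count ratios, volume-proxy biomass and
    signature biomass shares (full precision; round for display).
    """
    out = meta.copy()
    ccr = cell_count_ratios(out["dna_percent"], out["genome_mb"])
    out["cell_count_ratio_pct"] = ccr
    out["volume_proxy_biomass"] = volume_proxy_biomass(
        ccr, out["volume_um3"], normalize=normalize_volume)
    out["signature_biomass_pct"] = signature_biomass_shares(
        out["signature_tsm"])
    return out


def estimator_comparison(expected_pct: Mapping, estimates: Mapping[str, Mapping]
                         ) -> pd.DataFrame:
    """Side-by-side table of estimators with MAPE per method.

    `expected_pct` maps sample -> expected percent for the first reference;
    each entry of `estimates` maps sample -> estimated percent.
    """
    df = pd.DataFrame({"expected_pct": pd.Series(expected_pct)})
    for name, est in estimates.items():
        df[name] = pd.Series(est)
    df.attrs["mape"] = {
        name: mape(df[name].to_numpy(), df["expected_pct"].to_numpy())
        for name in estimates
    }
    return df
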