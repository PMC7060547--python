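"""Synthetic communities with the statistical structure the fit assumes.

The generator produces a taxon panel with ultrametric pairwise distances, a
set of reference organisms with ground-truth abundances, and TSM profiles
drawn from the signature mixture — optionally with Poisson (or
negative-binomial) count noise — so every stage of the pipeline can be
exercised end to end without any external data.  All randomness flows
through one seeded generator; identical seeds give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from phylopep.distances import DistanceMatrix
from phylopep.signature import (
    DEFAULT_A, DEFAULT_a, DEFAULT_b, SignatureParams, signature_value,
)
from phylopep.tsm import PsmRecord


@dataclass
class CommunityTruth:
    """Ground truth for one simulated community."""

    panel: list
    D: DistanceMatrix
    references: list
    abundances: dict          # ref -> N
    coefficients: dict = field(default_factory=dict)  # ref -> (A, a, b)
    noise: str = "poisson"    # "none" | "poisson" | "negbin"
    dispersion: float = 0.1   # negbin only: var = mu + dispersion * mu^2
    seed: int = 0

    def __post_init__(self):
        if not set(self.references) <= set(self.panel):
            raise ValueError("references must be panel members")
        if any(n < 0 for n in self.abundances.values()):
            raise ValueError("abundances must be non-negative")
        for ref in self.references:
            self.coefficients.setdefault(
                ref, (DEFAULT_A, DEFAULT_a, DEFAULT_b))
        if self.noise not in ("none", "poisson", "negbin"):
            raise ValueError(f"unknown noise model {self.noise!r}")

    @property
    def params(self) -> list[SignatureParams]:
        return [
            SignatureParams(ref, self.abundances[ref],
                            *self.coefficients[ref])
            for ref in self.references
        ]

    def to_json_dict(self) -> dict:
        return {
            "panel": [str(t) for t in self.panel],
            "references": [str(r) for r in self.references],
            "abundances": {str(k): v for k, v in self.abundances.items()},
            "coefficients": {str(k): list(v)
                             for k, v in self.coefficients.items()},
            "noise": self.noise,
            "seed": self.seed,
        }


def _random_ultrametric(n: int, rng: np.random.Generator) -> np.ndarray:
    """Pairwise distances from a random coalescent-style ultrametric tree.

    Clusters merge in random pairs at strictly increasing heights; the
    distance between two leaves is twice the height of their merge.
    """
    clusters: list[list[int]] = [[i] for i in range(n)]
    d = np.zeros((n, n))
    height = 0.0
    while len(clusters) > 1:
        height += rng.exponential(1.0 / len(clusters))
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        for a in clusters[i]:
            for b in clusters[j]:
                d[a, b] = d[b, a] = 2.0 * height
        clusters[i] = clusters[i] + clusters.pop(j)
    return d


def random_distance_panel(n_taxa: int, n_refs: int = 2, seed: int = 0,
                          spread: tuple[float, float] = (0.0, 0.5)
                          ) -> tuple[list, DistanceMatrix, list]:
    """Random taxon panel with ultrametric distances and spaced references.

    Distances are scaled so the largest equals ``spread[1]`` and off-diagonal
    entries are clipped up to ``spread[0]``.  References are picked by
    farthest-point selection so their signatures are distinguishable.
    Deterministic per seed.
    """
    lo, hi = spread
    if not (0 <= lo < hi <= 1):
        raise ValueError("spread must satisfy 0 <= min < max <= 1")
    if not 1 <= n_refs <= n_taxa:
        raise ValueError("need 1 <= n_refs <= n_taxa")
    rng = np.random.default_rng(seed)
    d = _random_ultrametric(n_taxa, rng)
    d *= hi / d.max()
    if lo > 0:
        off = ~np.eye(n_taxa, dtype=bool)
        d[off] = np.clip(d[off], lo, None)
    panel = [f"T{i:04d}" for i in range(n_taxa)]
    dm = DistanceMatrix(panel, d)

    # farthest-point reference selection, seeded at the global max pair
    i0, j0 = np.unravel_index(np.argmax(d), d.shape)
    refs_idx = [int(i0)]
    if n_refs > 1:
        refs_idx.append(int(j0))
    while len(refs_idx) < n_refs:
        mind = np.min(d[:, refs_idx], axis=1)
        mind[refs_idx] = -1
        refs_idx.append(int(np.argmax(mind)))
    refs = [panel[i] for i in sorted(refs_idx)]
    return panel, dm, refs


def simulate_tsm_profile(truth: CommunityTruth,
                         rng: np.random.Generator | None = None) -> pd.Series:
    """Draw one TSM profile over the panel from the signature mixture.

    noise="none" returns the real-valued expectations; "poisson" draws
    integer counts with those means; "negbin" adds overdispersion
    var = mu + dispersion * mu^2.
    """
    if rng is None:
        rng = np.random.default_rng(truth.seed)
    mu = np.zeros(len(truth.panel))
    for p in truth.params:
        x = np.array([truth.D.get(t, p.ref) for t in truth.panel])
        mu += signature_value(p, x)
    if truth.noise == "none":
        values = mu
    elif truth.noise == "poisson":
        values = rng.poisson(mu).astype(float)
    else:
        disp = truth.dispersion
        values = np.array([
            float(rng.poisson(rng.gamma(1.0 / disp, disp * m))) if m > 0
            else 0.0
            for m in mu
        ])
    return pd.Series(values, index=truth.panel, name="tsm")


def parse_ratio(ratio) -> tuple[float, ...]:
    """Accept '1:0.5' strings or numeric tuples."""
    if isinstance(ratio, str):
        return tuple(float(x) for x in ratio.split(":"))
    return tuple(float(x) for x in ratio)


def simulate_mixture_series(truth_template: CommunityTruth,
                            ratios: Sequence, total_tsms: int,
                            seed: int | None = None
                            ) -> tuple[list[pd.Series], pd.DataFrame]:
    """Profiles for a dilution series of reference mixtures.

    Each ratio r1:...:rk sets reference abundances proportional to the ratio
    and summing to `total_tsms`.  Returns the per-sample profiles plus a
    design table with the expected percentage of each reference, ready for
    MAPE / linearity scoring.
    """
    parsed = [parse_ratio(r) for r in ratios]
    k = len(truth_template.references)
    for r in parsed:
        if len(r) != k:
            raise ValueError(f"ratio {r} does not match {k} references")
        if any(x < 0 for x in r) or sum(r) == 0:
            raise ValueError(f"invalid ratio {r}")
    rng = np.random.default_rng(
        truth_template.seed if seed is None else seed)
    profiles, rows = [], []
    for sample, r in enumerate(parsed):
        total_r = sum(r)
        abund = {
            ref: total_tsms * x / total_r
            for ref, x in zip(truth_template.references, r)
        }
        truth = replace(truth_template, abundances=abund)
        profiles.append(simulate_tsm_profile(truth, rng))
        row = {"sample": sample, "ratio": ":".join(f"{x:g}" for x in r)}
        for ref, x in zip(truth.references, r):
            row[f"expected_pct_{ref}"] = 100.0 * x / total_r
            row[f"true_n_{ref}"] = abund[ref]
        rows.append(row)
    return profiles, pd.DataFrame(rows)


def _default_sharing(A: float = DEFAULT_A, a: float = DEFAULT_a,
                     b: float = DEFAULT_b) -> Callable[[float], float]:
    def sharing(x: float) -> float:
        return A * np.exp(-x / a) + (1 - A) * np.exp(-x / b)
    return sharing


@dataclass
class SyntheticPeptidome:
    """Toy peptidome: peptide -> taxa map plus sampled PSM records."""

    pep2tax: dict[str, frozenset]
    psms: list[PsmRecord]
    acc2tax: dict[str, frozenset]
    truth: CommunityTruth


def synthetic_peptidome(n_species: int, peptides_per_species: int,
                        shared_fraction_by_distance: Callable[[float], float]
                        | None = None,
                        seed: int = 0,
                        abundances: Sequence[float] | None = None,
                        spectra_per_species: int = 200
                        ) -> SyntheticPeptidome:
    """Generate a toy peptidome whose sharing decays with distance.

    Each species owns `peptides_per_species` peptides; a peptide of species k
    is also carried by species j with probability
    ``shared_fraction_by_distance(d_kj)`` (bi-exponential by default).  PSM
    records are then sampled per species proportionally to `abundances`,
    enabling end-to-end TSM-counting and fitting tests from the PSM level.
    """
    rng = np.random.default_rng(seed)
    sharing = shared_fraction_by_distance or _default_sharing()
    panel, dm, refs = random_distance_panel(n_species, min(2, n_species),
                                            seed=seed)
    if abundances is None:
        abundances = [float(spectra_per_species)] * n_species
    alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

    pep2tax: dict[str, set] = {}
    acc2tax: dict[str, set] = {}
    peptides_of: dict[str, list[str]] = {sp: [] for sp in panel}
    for ki, owner in enumerate(panel):
        for pi in range(peptides_per_species):
            pep = "".join(rng.choice(alphabet, size=12))
            members = {owner}
            for kj, other in enumerate(panel):
                if other == owner:
                    continue
                if rng.random() < sharing(dm.d[ki, kj]):
                    members.add(other)
            pep2tax.setdefault(pep, set()).update(members)
            for m in members:
                acc = f"{pep[:6]}_{m}"
                acc2tax.setdefault(acc, set()).add(m)
                peptides_of[m].append(pep)

    psms: list[PsmRecord] = []
    spectrum = 0
    for sp, n in zip(panel, abundances):
        draws = rng.poisson(n) if n > 0 else 0
        pool = peptides_of[sp]
        if not pool:
            continue
        for _ in range(draws):
            pep = pool[rng.integers(len(pool))]
            accs = tuple(sorted(
                f"{pep[:6]}_{m}" for m in pep2tax[pep]))
            psms.append(PsmRecord(f"S{spectrum:06d}", pep, 1e-3, accs))
            spectrum += 1

    truth = CommunityTruth(
        panel=panel, D=dm, references=refs,
        abundances={r: float(abundances[panel.index(r)]) for r in refs},
        noise="poisson", seed=seed)
    return SyntheticPeptidome(
        {p: frozenset(t) for p, t in pep2tax.items()}, psms,
        {a: frozenset(t) for a, t in acc2tax.items()}, truth)
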