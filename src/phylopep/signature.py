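"""The phylopeptidomic signature model and its bounded least-squares fit.

A reference organism present at TSM-scale abundance N projects shared-peptide
spectral counts onto every other taxon i as a function of their phylogenetic
distance x:

    y(x) = N * (A * exp(-x / a) + (1 - A) * exp(-x / b)),

with A in [0, 1] splitting the signal between a fast decay (coefficient a,
near-identical strains) and a slow decay (coefficient b, more distant
relatives).  A community's observed TSM profile is the sum of the signatures
of the organisms actually present; fitting that sum by bound-constrained
least squares recovers each N_k free of shared-peptide double counting.

The fit is exposed statsmodels-style: :class:`SignatureMixtureModel` is built
from the observed profile and a distance matrix, ``fit()`` returns a
:class:`SignatureMixtureResults` carrying parameters, ratios, residuals,
approximate standard errors and a ``summary()`` table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from phylopep.distances import DistanceMatrix
from phylopep.tsm import TsmTable, ASSIGNED_RANK

DEFAULT_A = 0.45
DEFAULT_a = 0.013
DEFAULT_b = 0.082


@dataclass(frozen=True)
class SignatureParams:
    """Fitted (or assumed) signature of one reference organism."""

    ref: object
    N: float
    A: float = DEFAULT_A
    a: float = DEFAULT_a
    b: float = DEFAULT_b

    def __post_init__(self):
        if self.N < 0:
            raise ValueError("N must be non-negative")
        if not 0 <= self.A <= 1:
            raise ValueError("A must be in [0, 1]")
        if self.a <= 0 or self.b <= 0:
            raise ValueError("decay coefficients a, b must be positive")


def signature_value(p: SignatureParams, x) -> float | np.ndarray:
    """Expected TSM count of a taxon at distance x from the reference.

    Equals N at x = 0 and decreases strictly with distance.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("distance must be non-negative")
    y = p.N * (p.A * np.exp(-x / p.a) + (1.0 - p.A) * np.exp(-x / p.b))
    return float(y) if y.ndim == 0 else y


def mixture_value(params: Sequence[SignatureParams], D: DistanceMatrix,
                  taxon) -> float:
    """Summed expected TSM count at `taxon` over all reference signatures.

    A reference's own position receives its full N plus the other references'
    shared-peptide leakage.
    """
    return float(sum(signature_value(p, D.get(taxon, p.ref)) for p in params))


@dataclass(frozen=True)
class FitSpec:
    """Defaults, bounds, scaling and termination for the signature fit.

    The optimizer explores a normalised space where each parameter is divided
    by its characteristic scale (A0, a0, b0, and 100 for N), so one
    termination tolerance applies to all of them.
    """

    references: tuple = ()
    A0: float = DEFAULT_A
    a0: float = DEFAULT_a
    b0: float = DEFAULT_b
    dA: float = 0.05
    da: float = 0.001
    db: float = 0.001
    n_bound_factor: float = 5.0
    n_scale: float = 100.0
    tol: float = 0.01

    def __post_init__(self):
        if self.tol <= 0:
            raise ValueError("tolerance must be positive")
        if not (0 <= self.A0 - self.dA and self.A0 + self.dA <= 1):
            raise ValueError("A bounds must stay inside [0, 1]")
        if self.a0 - self.da <= 0 or self.b0 - self.db <= 0:
            raise ValueError("a, b bounds must stay positive")


class SignatureMixtureModel:
    """Bounded least-squares deconvolution of a TSM profile.

    Parameters
    ----------
    counts : mapping or pandas Series
        Observed TSM count per panel taxon.
    distances : DistanceMatrix
        Pairwise distances covering the panel and the references.
    references : sequence
        The organisms whose abundances are to be recovered; must be panel
        members of `distances`.
    spec : FitSpec, optional
        Fit configuration; defaults follow the standard signature-fit setup.
    """

    def __init__(self, counts, distances: DistanceMatrix,
                 references: Sequence, spec: FitSpec | None = None):
        if isinstance(counts, Mapping):
            counts = pd.Series(counts)
        elif not isinstance(counts, pd.Series):
            raise TypeError("counts must be a mapping or pandas Series")
        self.counts = counts.astype(float)
        self.distances = distances
        self.references = list(references)
        if not self.references:
            raise ValueError("at least one reference is required")
        for ref in self.references:
            if ref not in distances:
                raise KeyError(f"reference {ref!r} absent from the distance "
                               "matrix")
        missing = [t for t in self.counts.index if t not in distances]
        if missing:
            raise KeyError(f"panel taxa absent from the distance matrix: "
                           f"{missing[:5]}")
        if not (self.counts > 0).any():
            raise ValueError("no MS/MS attribution: all observed counts are "
                             "zero")
        self.spec = spec if spec is not None else FitSpec()
        self.panel = list(self.counts.index)
        self.y = self.counts.to_numpy()
        # distance of every panel taxon to every reference
        self.X = np.column_stack([
            np.array([distances.get(t, ref) for t in self.panel])
            for ref in self.references
        ])
        k = len(self.references)
        if len(self.panel) < k:
            warnings.warn(
                f"panel of {len(self.panel)} taxa for {4 * k} free "
                "parameters; the fit may be under-determined", stacklevel=2)
        self._check_degeneracy()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, distances: DistanceMatrix,
                       references: Sequence, taxon_col: str = "taxon",
                       count_col: str = "tsm",
                       spec: FitSpec | None = None) -> "SignatureMixtureModel":
        counts = df.set_index(taxon_col)[count_col]
        return cls(counts, distances, references, spec)

    @classmethod
    def from_tsm_table(cls, table: TsmTable, distances: DistanceMatrix,
                       references: Sequence, rank: str = ASSIGNED_RANK,
                       panel: Sequence | None = None,
                       spec: FitSpec | None = None) -> "SignatureMixtureModel":
        sub = table.df[table.df["rank"] == rank].set_index("taxid")["tsm"]
        if panel is not None:
            sub = sub.reindex(panel).fillna(0)
        return cls(sub, distances, references, spec)

    # -- internals ---------------------------------------------------------

    def _check_degeneracy(self) -> None:
        """Warn when reference signatures are nearly collinear on this panel."""
        if len(self.references) < 2:
            return
        cols = []
        for j, _ in enumerate(self.references):
            p = SignatureParams("tmp", 1.0, self.spec.A0, self.spec.a0,
                                self.spec.b0)
            cols.append(signature_value(p, self.X[:, j]))
        M = np.column_stack(cols)
        norms = np.linalg.norm(M, axis=0)
        if np.any(norms == 0):
            warnings.warn("a reference signature is identically zero on this "
                          "panel", stacklevel=3)
            return
        cond = np.linalg.cond(M / norms)
        if cond > 1e4:
            warnings.warn(
                f"reference signatures are nearly collinear (condition number "
                f"{cond:.2g}); the abundance split may be unidentifiable",
                stacklevel=3)

    def _start(self) -> np.ndarray:
        """Per-reference start point (N, A, a, b); N starts at the observed
        TSM count of the reference itself."""
        s = self.spec
        theta0 = []
        for j, ref in enumerate(self.references):
            n0 = float(self.counts.get(ref, 0.0))
            if n0 == 0.0:
                # reference not observed directly: seed from the panel maximum
                n0 = float(self.y.max())
            theta0.extend([n0, s.A0, s.a0, s.b0])
        return np.asarray(theta0)

    def _scales(self) -> np.ndarray:
        s = self.spec
        return np.tile([s.n_scale, s.A0, s.a0, s.b0], len(self.references))

    def _bounds(self, theta0: np.ndarray) -> list[tuple[float, float]]:
        s = self.spec
        bounds = []
        for j in range(len(self.references)):
            n0 = theta0[4 * j]
            bounds.append((0.0, s.n_bound_factor * max(n0, 1.0)))
            bounds.append((s.A0 - s.dA, s.A0 + s.dA))
            bounds.append((s.a0 - s.da, s.a0 + s.da))
            bounds.append((s.b0 - s.db, s.b0 + s.db))
        return bounds

    def predict(self, params: Sequence[SignatureParams] | np.ndarray
                ) -> np.ndarray:
        """Model TSM counts over the panel for a parameter set."""
        theta = (np.asarray(params, dtype=float)
                 if not isinstance(params[0], SignatureParams)
                 else np.concatenate([[p.N, p.A, p.a, p.b] for p in params]))
        return self._predict_theta(theta)

    def _predict_theta(self, theta: np.ndarray) -> np.ndarray:
        yhat = np.zeros(len(self.panel))
        for j in range(len(self.references)):
            N, A, a, b = theta[4 * j:4 * j + 4]
            x = self.X[:, j]
            yhat += N * (A * np.exp(-x / a) + (1 - A) * np.exp(-x / b))
        return yhat

    def _objective_grad(self, theta: np.ndarray
                        ) -> tuple[float, np.ndarray]:
        r = self._predict_theta(theta) - self.y
        grad = np.empty_like(theta)
        for j in range(len(self.references)):
            N, A, a, b = theta[4 * j:4 * j + 4]
            x = self.X[:, j]
            ea, eb = np.exp(-x / a), np.exp(-x / b)
            base = A * ea + (1 - A) * eb
            grad[4 * j + 0] = 2 * r @ base
            grad[4 * j + 1] = 2 * r @ (N * (ea - eb))
            grad[4 * j + 2] = 2 * r @ (N * A * ea * x / a ** 2)
            grad[4 * j + 3] = 2 * r @ (N * (1 - A) * eb * x / b ** 2)
        return float(r @ r), grad

    def fit(self, start: Sequence[SignatureParams] | None = None
            ) -> "SignatureMixtureResults":
        """Minimise the sum of squared residuals with L-BFGS-B.

        Deterministic: the start point is the spec's defaults (or `start`),
        never random.
        """
        theta0 = self._start()
        if start is not None:
            theta0 = np.concatenate([[p.N, p.A, p.a, p.b] for p in start])
        scales = self._scales()
        bounds = self._bounds(self._start())
        zbounds = [(lo / s, hi / s) for (lo, hi), s in zip(bounds, scales)]

        def fun(z):
            val, grad = self._objective_grad(z * scales)
            return val, grad * scales

        res = minimize(fun, theta0 / scales, jac=True, method="L-BFGS-B",
                       bounds=zbounds, tol=self.spec.tol,
                       options={"maxiter": 500})
        theta = res.x * scales
        params = [
            SignatureParams(ref, *theta[4 * j:4 * j + 4])
            for j, ref in enumerate(self.references)
        ]
        residuals = pd.Series(self.y - self._predict_theta(theta),
                              index=self.panel, name="residual")
        return SignatureMixtureResults(
            model=self, params=params,
            objective=float(residuals.to_numpy() @ residuals.to_numpy()),
            residuals=residuals, success=bool(res.success),
            n_iter=int(res.nit), message=str(res.message))


@dataclass
class SignatureMixtureResults:
    """Fitted signature mixture: per-reference parameters and diagnostics."""

    model: SignatureMixtureModel
    params: list[SignatureParams]
    objective: float
    residuals: pd.Series
    success: bool = True
    n_iter: int = 0
    message: str = ""
    _bse: pd.Series | None = field(default=None, repr=False)

    @property
    def nobs(self) -> int:
        return len(self.model.panel)

    @property
    def abundances(self) -> pd.Series:
        return pd.Series({p.ref: p.N for p in self.params}, name="N")

    @property
    def ratios(self) -> pd.Series:
        """Relative abundance of each reference in percent (sums to 100)."""
        n = self.abundances
        total = n.sum()
        if total <= 0:
            raise ValueError("all fitted abundances are zero")
        return 100.0 * n / total

    @property
    def fittedvalues(self) -> pd.Series:
        return pd.Series(self.model.predict(self.params),
                         index=self.model.panel, name="fitted")

    @property
    def bse(self) -> pd.Series:
        """Linearised (Gauss-Newton) standard errors of the N_k.

        Approximate: treats the decay coefficients as fixed at their fitted
        values and may understate uncertainty when a bound is active.
        """
        if self._bse is None:
            cols = [
                signature_value(replace(p, N=1.0), self.model.X[:, j])
                for j, p in enumerate(self.params)
            ]
            J = np.column_stack(cols)
            dof = max(self.nobs - 4 * len(self.params), 1)
            s2 = self.objective / dof
            cov = s2 * np.linalg.pinv(J.T @ J)
            self._bse = pd.Series(np.sqrt(np.maximum(np.diag(cov), 0.0)),
                                  index=[p.ref for p in self.params],
                                  name="bse")
        return self._bse

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "ref": [p.ref for p in self.params],
            "N": [p.N for p in self.params],
            "A": [p.A for p in self.params],
            "a": [p.a for p in self.params],
            "b": [p.b for p in self.params],
            "ratio_pct": self.ratios.to_numpy(),
            "se_N": self.bse.to_numpy(),
        })

    def summary(self) -> str:
        lines = [
            "Phylopeptidomic signature mixture fit",
            "=" * 61,
            f"panel taxa: {self.nobs}    references: {len(self.params)}",
            f"objective (SSR): {self.objective:.6g}    iterations: "
            f"{self.n_iter}    converged: {self.success}",
            "-" * 61,
            f"{'ref':>12} {'N':>10} {'se(N)':>8} {'A':>6} {'a':>7} "
            f"{'b':>7} {'ratio%':>7}",
        ]
        for p, se, r in zip(self.params, self.bse, self.ratios):
            lines.append(
                f"{str(p.ref):>12} {p.N:>10.1f} {se:>8.1f} {p.A:>6.3f} "
                f"{p.a:>7.4f} {p.b:>7.4f} {r:>7.1f}")
        lines.append("=" * 61)
        return "\n".join(lines)

    def plot(self, reference=None, ax=None, log_y: bool = True):
        """Observed vs fitted TSMs along one reference's distance axis."""
        import matplotlib.pyplot as plt

        if reference is None:
            reference = self.params[0].ref
        j = self.model.references.index(reference)
        x = self.model.X[:, j]
        if ax is None:
            _, ax = plt.subplots()
        order = np.argsort(x)
        ax.scatter(x, self.model.y, s=12, color="k", label="observed TSMs")
        ax.plot(x[order], self.fittedvalues.to_numpy()[order], color="C1",
                label="fitted mixture")
        for p in self.params:
            jj = self.model.references.index(p.ref)
            ax.plot(x[order],
                    signature_value(p, self.model.X[order, jj]),
                    "--", alpha=0.6, label=f"signature {p.ref}")
        if log_y:
            ax.set_yscale("symlog", linthresh=1)
        ax.set_xlabel(f"phylogenetic distance to {reference}")
        ax.set_ylabel("TSM count")
        ax.legend(fontsize=8)
        return ax

    def write_report(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def filter_fit_taxa(table: TsmTable, metadata: pd.DataFrame,
                    rank: str = ASSIGNED_RANK) -> list:
    """Panel selection for the fit: taxa with MS/MS attribution, fewer than
    10 missing marker COGs, and a "Complete genome" assembly.

    `metadata` columns: taxid, missing_cogs, assembly_level.  Taxa without
    metadata are excluded (tallied in the log).
    """
    meta = metadata.set_index("taxid")
    sub = table.df[(table.df["rank"] == rank) & (table.df["tsm"] > 0)]
    panel, skipped = [], 0
    for taxid in sub["taxid"]:
        if taxid not in meta.index:
            skipped += 1
            continue
        row = meta.loc[taxid]
        if row["missing_cogs"] < 10 and row["assembly_level"] == "Complete genome":
            panel.append(taxid)
    if skipped:
        warnings.warn(f"{skipped} taxa lacked metadata and were excluded",
                      stacklevel=2)
    return panel


def fit_signatures(observed, D: DistanceMatrix,
                   spec: FitSpec | None = None,
                   references: Sequence | None = None
                   ) -> SignatureMixtureResults:
    """Functional entry point: fit a signature mixture to an observed profile.

    `observed` may be a mapping/Series taxon -> TSM count or a sequence of
    (taxon, count) pairs.  References default to ``spec.references``.
    """
    if not isinstance(observed, (Mapping, pd.Series)):
        observed = dict(observed)
    refs = list(references) if references is not None else (
        list(spec.references) if spec is not None else [])
    model = SignatureMixtureModel(observed, D, refs, spec)
    return model.fit()
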