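"""Positive-unlabeled logistic regression for sorted-vs-input screens.

The sorted pool is a sample of (mostly) active variants ("positive"); the
presorted input pool is an unlabeled mixture in which a known fraction
``prior_pi`` is active. Under case-control sampling, the probability that an
observation with features ``x`` came from the sorted pool is

    q(x) = n_P * sigma(x) / (n_P * sigma(x) + n_U * pi),
    sigma(x) = logistic(beta0 + x . beta),

and the per-substitution slopes ``beta`` are estimated by maximizing the
conditional likelihood of pool membership. Negative slopes mark deleterious
substitutions; positive slopes mark neutral or activating ones.

The model API follows the statsmodels convention: construct a
:class:`PULogisticModel` from data, call :meth:`~PULogisticModel.fit`, and
read estimates off the returned :class:`PULogisticResults`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import minimize
from scipy.special import expit

from .calling import MutationCountTable
from .sequences import substitution_key
from .synth import SubKey

logger = logging.getLogger(__name__)

_EPS = 1e-12
DEFAULT_L2 = 1e-4
DEFAULT_TOL = 1e-8
DEFAULT_MAX_ITER = 500
DEFAULT_CAP = 10.0


@dataclass
class FeatureMatrix:
    """Binary substitution indicators per read with a pool label.

    ``X[i, j] = 1`` iff read ``i`` carries retained substitution ``j``;
    ``z[i] = 1`` for sorted-pool reads, 0 for input-pool reads.
    """

    X: sparse.csr_matrix
    z: np.ndarray
    feature_names: list[SubKey]
    counts: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        if self.X.shape[0] != len(self.z):
            raise ValueError("X and z disagree on the number of observations")
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError("X and feature_names disagree on feature count")
        data = self.X.data
        if data.size and not np.isin(data, (0.0, 1.0)).all():
            raise ValueError("feature entries must be binary")

    @property
    def n_obs(self) -> int:
        return self.X.shape[0]

    @property
    def n_pos(self) -> int:
        return int(self.z.sum())

    @property
    def n_unl(self) -> int:
        return int(len(self.z) - self.z.sum())

    @classmethod
    def from_read_calls(
        cls,
        input_calls: list[list[SubKey] | None],
        sorted_calls: list[list[SubKey] | None],
        retained: list[SubKey],
    ) -> "FeatureMatrix":
        """Build the read-by-substitution indicator matrix.

        ``retained`` fixes the feature set (typically the count-thresholded
        substitutions); substitutions outside it are ignored. Rejected reads
        (None entries) are skipped.
        """
        index = {s: j for j, s in enumerate(retained)}
        rows, cols, z = [], [], []
        i = 0
        for calls, label in ((sorted_calls, 1), (input_calls, 0)):
            for subs in calls:
                if subs is None:
                    continue
                for s in subs:
                    j = index.get(s)
                    if j is not None:
                        rows.append(i)
                        cols.append(j)
                z.append(label)
                i += 1
        X = sparse.csr_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(i, len(retained))
        )
        X.sum_duplicates()
        X.data[:] = 1.0
        return cls(X=X, z=np.asarray(z, dtype=float), feature_names=list(retained))


def pu_negative_log_likelihood(
    beta0: float,
    beta: np.ndarray,
    features: FeatureMatrix,
    prior_pi: float,
    l2_penalty: float = 0.0,
) -> tuple[float, np.ndarray]:
    """Objective and exact gradient of the case-control PU likelihood.

    Returns ``(objective, gradient)`` with the gradient ordered as
    ``[d/dbeta0, d/dbeta]``. An optional L2 penalty applies to slopes only.
    """
    if not 0 < prior_pi < 1:
        raise ValueError("prior_pi must lie in (0, 1)")
    beta = np.asarray(beta, dtype=float)
    z = features.z
    nP, nU = features.n_pos, features.n_unl
    eta = beta0 + features.X @ beta
    sig = expit(eta)
    denom = nP * sig + nU * prior_pi
    q = nP * sig / denom
    qc = np.clip(q, _EPS, 1.0 - _EPS)
    if np.any(q <= _EPS) or np.any(q >= 1.0 - _EPS):
        logger.warning("PU likelihood: %d membership probabilities clamped",
                       int(((q <= _EPS) | (q >= 1.0 - _EPS)).sum()))
    nll = -float(z @ np.log(qc) + (1.0 - z) @ np.log1p(-qc))
    d_eta = -(1.0 - sig) * (z - q)
    grad = np.empty(len(beta) + 1)
    grad[0] = d_eta.sum()
    grad[1:] = features.X.T @ d_eta
    if l2_penalty:
        nll += l2_penalty * float(beta @ beta)
        grad[1:] += 2.0 * l2_penalty * beta
    return nll, grad


class CoefficientTable:
    """Fitted per-substitution coefficients with metadata.

    ``df`` is indexed by (position, ref, alt) and carries ``beta`` plus
    optional ``se``, ``count_input`` and ``count_sorted`` columns.
    """

    def __init__(self, df: pd.DataFrame, intercept: float = 0.0,
                 metadata: dict | None = None):
        self.df = df.sort_index()
        self.intercept = float(intercept)
        self.metadata = dict(metadata or {})

    def __len__(self) -> int:
        return len(self.df)

    @property
    def beta(self) -> pd.Series:
        return self.df["beta"]

    def to_tsv(self, path) -> None:
        out = self.df.reset_index()
        out.insert(0, "substitution",
                   [substitution_key(p, r, a) for p, r, a in self.df.index])
        out.to_csv(path, sep="\t", index=False, float_format="%.6g")

    @classmethod
    def from_tsv(cls, path) -> "CoefficientTable":
        raw = pd.read_csv(path, sep="\t")
        idx = pd.MultiIndex.from_arrays(
            [raw["position"], raw["ref"], raw["alt"]],
            names=["position", "ref", "alt"],
        )
        df = raw.drop(columns=["substitution", "position", "ref", "alt"],
                      errors="ignore")
        df.index = idx
        return cls(df)


class PULogisticResults:
    """Estimates from a fitted :class:`PULogisticModel`."""

    def __init__(self, model: "PULogisticModel", intercept: float,
                 params: np.ndarray, bse: np.ndarray | None,
                 converged: bool, n_iter: int, objective: float,
                 capped: np.ndarray):
        self.model = model
        self.intercept = float(intercept)
        self.params = pd.Series(
            params,
            index=[substitution_key(*s) for s in model.features.feature_names],
            name="beta",
        )
        self.bse = (
            pd.Series(bse, index=self.params.index, name="se")
            if bse is not None else None
        )
        self.converged = bool(converged)
        self.n_iter = int(n_iter)
        self.objective = float(objective)
        self.capped = capped

    def predict_activity(self, X: sparse.spmatrix | np.ndarray) -> np.ndarray:
        """P(active | features) under the fitted logistic model."""
        return expit(self.intercept + X @ self.params.to_numpy())

    def coefficient_table(self) -> CoefficientTable:
        feats = self.model.features
        idx = pd.MultiIndex.from_tuples(feats.feature_names,
                                        names=["position", "ref", "alt"])
        df = pd.DataFrame({"beta": self.params.to_numpy()}, index=idx)
        if self.bse is not None:
            df["se"] = self.bse.to_numpy()
        Xc = feats.X.tocsc()
        zcol = feats.z
        occ_sorted = np.asarray(
            Xc.multiply(zcol[:, None]).sum(axis=0)
        ).ravel()
        occ_total = np.asarray(Xc.sum(axis=0)).ravel()
        df["count_sorted"] = occ_sorted.astype(int)
        df["count_input"] = (occ_total - occ_sorted).astype(int)
        meta = {
            "prior_pi": self.model.prior_pi,
            "l2_penalty": self.model._fit_opts.get("l2_penalty"),
            "converged": self.converged,
            "n_iter": self.n_iter,
            "objective": self.objective,
        }
        return CoefficientTable(df, intercept=self.intercept, metadata=meta)

    def summary(self) -> str:
        lines = [
            "Positive-Unlabeled Logistic Regression Results",
            "=" * 54,
            f"No. observations: {self.model.features.n_obs}"
            f"   sorted: {self.model.features.n_pos}"
            f"   input: {self.model.features.n_unl}",
            f"Class prior pi:   {self.model.prior_pi:.4f}",
            f"Converged:        {self.converged}   iterations: {self.n_iter}",
            f"Objective:        {self.objective:.6g}",
            f"Intercept beta0:  {self.intercept:+.4f}",
            "-" * 54,
            f"{'substitution':<14}{'beta':>10}{'se':>10}",
        ]
        se = self.bse if self.bse is not None else pd.Series(np.nan, index=self.params.index)
        for name, b in self.params.items():
            lines.append(f"{name:<14}{b:>10.4f}{se[name]:>10.4f}")
        return "\n".join(lines)


class PULogisticModel:
    """Case-control positive-unlabeled logistic regression with known prior.

    Parameters
    ----------
    features : FeatureMatrix
        Read-level binary substitution indicators with pool labels.
    prior_pi : float
        Fraction of the unlabeled input population that is truly active
        (measured externally, e.g. by a plate-based activity assay).
    """

    def __init__(self, features: FeatureMatrix, prior_pi: float = 0.25):
        if features.n_obs == 0 or len(features.feature_names) == 0:
            raise ValueError("features must be non-empty")
        if not 0 < prior_pi < 1:
            raise ValueError("prior_pi must lie in (0, 1)")
        if features.n_pos == 0 or features.n_unl == 0:
            raise ValueError("both pools must be represented in the observations")
        self.features = features
        self.prior_pi = float(prior_pi)
        self._fit_opts: dict = {}

    @classmethod
    def from_count_pipeline(cls, input_calls, sorted_calls,
                            table: MutationCountTable,
                            prior_pi: float = 0.25) -> "PULogisticModel":
        fm = FeatureMatrix.from_read_calls(input_calls, sorted_calls,
                                           table.substitutions)
        return cls(fm, prior_pi=prior_pi)

    def nloglike(self, params: np.ndarray, l2_penalty: float = 0.0):
        return pu_negative_log_likelihood(
            params[0], params[1:], self.features, self.prior_pi, l2_penalty
        )

    def fit(
        self,
        l2_penalty: float = DEFAULT_L2,
        tol: float = DEFAULT_TOL,
        max_iter: int = DEFAULT_MAX_ITER,
        cap: float = DEFAULT_CAP,
        start_params: np.ndarray | None = None,
        compute_se: bool = True,
    ) -> PULogisticResults:
        """Minimize the PU negative log-likelihood by L-BFGS-B.

        Slopes are box-bounded at ``±cap`` so separable substitutions (seen
        in only one pool) return a capped, flagged coefficient instead of
        diverging. The converged flag mirrors the optimizer's relative
        objective-decrease test at ``tol``.
        """
        p = len(self.features.feature_names)
        x0 = np.zeros(p + 1) if start_params is None else np.asarray(start_params, float)
        self._fit_opts = {"l2_penalty": l2_penalty, "tol": tol,
                          "max_iter": max_iter, "cap": cap}
        bounds = [(None, None)] + [(-cap, cap)] * p

        res = minimize(
            lambda v: pu_negative_log_likelihood(
                v[0], v[1:], self.features, self.prior_pi, l2_penalty
            ),
            x0,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-10},
        )
        beta0, beta = float(res.x[0]), res.x[1:]
        capped = np.abs(beta) >= cap - 1e-9
        if capped.any():
            warnings.warn(
                f"{int(capped.sum())} separable substitution(s) hit the ±{cap} "
                "coefficient cap", RuntimeWarning, stacklevel=2,
            )
        converged = bool(res.success)
        bse = None
        if compute_se and p <= 2000:
            bse = self._standard_errors(beta0, beta, l2_penalty)
        return PULogisticResults(self, beta0, beta, bse, converged,
                                 int(res.nit), float(res.fun), capped)

    def _standard_errors(self, beta0, beta, l2_penalty) -> np.ndarray | None:
        """Slope SEs from the analytic Hessian of the (penalized) objective."""
        f = self.features
        eta = beta0 + f.X @ beta
        sig = expit(eta)
        nP, nU = f.n_pos, f.n_unl
        q = nP * sig / (nP * sig + nU * self.prior_pi)
        w = sig * (1 - sig) * (f.z - q) + (1 - sig) ** 2 * q * (1 - q)
        ones = np.ones((f.n_obs, 1))
        A = sparse.hstack([sparse.csr_matrix(ones), f.X]).tocsr()
        H = (A.T @ sparse.diags(w) @ A).toarray()
        H[1:, 1:] += 2.0 * l2_penalty * np.eye(len(beta))
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            return None
        d = np.diag(cov)[1:]
        with np.errstate(invalid="ignore"):
            return np.sqrt(np.where(d > 0, d, np.nan))


def fit_pu_logistic(
    features: FeatureMatrix,
    prior_pi: float = 0.25,
    l2_penalty: float = DEFAULT_L2,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    seed: int = 0,
) -> CoefficientTable:
    """Functional wrapper: fit the PU model and return its CoefficientTable.

    The fit itself is deterministic; ``seed`` is accepted for interface
    symmetry with the stochastic stages and recorded in the metadata.
    """
    res = PULogisticModel(features, prior_pi=prior_pi).fit(
        l2_penalty=l2_penalty, tol=tol, max_iter=max_iter
    )
    table = res.coefficient_table()
    table.metadata["seed"] = seed
    return table


def naive_log_enrichment(table: MutationCountTable, pseudocount: float = 0.5) -> CoefficientTable:
    """Diagnostic per-substitution log enrichment (sorted vs input frequency).

    ``log[(c_s + a)/(N_s + a)] - log[(c_i + a)/(N_i + a)]`` with pseudocount
    ``a``. Used as a model-free cross-check on the PU fit's signs.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    a = pseudocount
    Ns = table.totals.get("sorted", 0)
    Ni = table.totals.get("input", 0)
    cs = table.df["count_sorted"].to_numpy(dtype=float)
    ci = table.df["count_input"].to_numpy(dtype=float)
    beta = np.log((cs + a) / (Ns + a)) - np.log((ci + a) / (Ni + a))
    df = pd.DataFrame(
        {"beta": beta, "count_input": ci.astype(int), "count_sorted": cs.astype(int)},
        index=table.df.index,
    )
    return CoefficientTable(df, metadata={"method": "log_enrichment",
                                          "pseudocount": a})


def replicate_concordance(
    tables: list[CoefficientTable],
    exclusion_threshold: float = 0.5,
) -> tuple[pd.DataFrame, list[int]]:
    """Pearson correlations between replicate coefficient tables.

    Correlations are computed on the substitutions shared by all tables.
    With at least three replicates, outliers are excluded greedily: while
    any replicate's mean correlation with the *remaining* replicates falls
    below the threshold, the worst one is dropped and the means recomputed
    (a single noise replicate otherwise drags the good ones' means down with
    it). With only two replicates there is no way to tell which one is at
    fault, so nothing is excluded.
    """
    if len(tables) < 2:
        raise ValueError("need at least 2 replicate tables")
    shared = tables[0].df.index
    for t in tables[1:]:
        shared = shared.intersection(t.df.index)
    if len(shared) < 20:
        raise ValueError(
            f"replicates share only {len(shared)} substitutions (< 20)"
        )
    mat = np.column_stack([t.df.loc[shared, "beta"].to_numpy() for t in tables])
    corr = pd.DataFrame(np.corrcoef(mat, rowvar=False),
                        index=range(1, len(tables) + 1),
                        columns=range(1, len(tables) + 1))
    excluded: list[int] = []
    remaining = list(range(len(tables)))
    C = corr.to_numpy()
    while len(remaining) >= 3:
        sub = C[np.ix_(remaining, remaining)]
        mean_off = (sub.sum(axis=1) - 1.0) / (len(remaining) - 1)
        worst = int(np.argmin(mean_off))
        if mean_off[worst] >= exclusion_threshold:
            break
        excluded.append(remaining.pop(worst) + 1)
    return corr, sorted(excluded)


def combine_replicates(
    tables: list[CoefficientTable], excluded: list[int] | None = None
) -> CoefficientTable:
    """Count-weighted mean of replicate coefficients after exclusion."""
    excluded = set(excluded or [])
    kept = [t for i, t in enumerate(tables, start=1) if i not in excluded]
    if not kept:
        raise ValueError("all replicates excluded")
    frames = []
    for t in kept:
        d = t.df.copy()
        if "count_input" in d and "count_sorted" in d:
            d["_w"] = d["count_input"] + d["count_sorted"]
        else:
            d["_w"] = 1.0
        frames.append(d[["beta", "_w"]])
    allidx = frames[0].index
    for f in frames[1:]:
        allidx = allidx.union(f.index)
    num = pd.Series(0.0, index=allidx)
    den = pd.Series(0.0, index=allidx)
    for f in frames:
        num = num.add(f["beta"] * f["_w"], fill_value=0.0)
        den = den.add(f["_w"], fill_value=0.0)
    beta = num / den.replace(0.0, np.nan)
    df = pd.DataFrame({"beta": beta, "n_reads": den.astype(int)}).dropna(subset=["beta"])
    df.index.names = ["position", "ref", "alt"]
    meta = {"n_replicates": len(kept), "excluded": sorted(excluded)}
    return CoefficientTable(df, metadata=meta)
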