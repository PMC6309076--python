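"""Model / Results interface for differential network estimation.

`DifferentialNetwork` is constructed from two groups' data and a
correlation rule ('rank' for the latent Gaussian-copula estimator,
'pearson' for the plain direct estimator); `fit()` returns a
`DifferentialNetworkResults` carrying the estimated difference of the
latent precision matrices, the tuning trace, solver diagnostics, and a
`summary()` table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import DataMatrix
from .rank import latent_correlation, pearson_correlation
from .selection import aic_select, loss_value, make_aic_early_stop
from .solver import (
    DifferenceProblem,
    admm_solve,
    default_lambda_grid,
    solve_path,
    threshold_support,
)

__all__ = ["DifferentialNetwork", "DifferentialNetworkResults"]


class DifferentialNetwork:
    """Differential (latent) network model for two-group data.

    Parameters
    ----------
    data1, data2 : DataMatrix, DataFrame or (n, p) array
        The two groups' observations; same variables in both groups.
    var_types : 'auto', 'continuous', 'binary', or sequence
        Per-variable types (shared across groups).
    method : {'rank', 'pearson'}
        'rank' uses Kendall-tau bridge inversion to estimate the latent
        correlation matrices (valid for continuous, binary and mixed
        data); 'pearson' uses sample Pearson correlation of the observed
        values (the non-latent baseline).

    Examples
    --------
    >>> model = DifferentialNetwork(df_cases, df_controls, var_types="auto")
    >>> res = model.fit(loss="F")
    >>> res.edges()
    """

    def __init__(self, data1, data2, var_types="auto", method="rank"):
        self.data1 = self._coerce(data1, var_types, "group1")
        self.data2 = self._coerce(data2, var_types, "group2")
        if self.data1.p != self.data2.p:
            raise ValueError("the two groups must share the same variables")
        if self.data1.names != self.data2.names:
            raise ValueError("variable names differ between groups")
        if method not in ("rank", "pearson"):
            raise ValueError("method must be 'rank' or 'pearson'")
        self.method = method
        estimate = latent_correlation if method == "rank" else pearson_correlation
        self.corr1 = estimate(self.data1)
        self.corr2 = estimate(self.data2)
        self.problem = DifferenceProblem(self.corr1.matrix, self.corr2.matrix)

    @staticmethod
    def _coerce(data, var_types, label):
        if isinstance(data, DataMatrix):
            return data
        if isinstance(data, pd.DataFrame):
            return DataMatrix.from_dataframe(data, types=var_types,
                                             group_label=label)
        return DataMatrix(np.asarray(data, float), types=var_types,
                          group_label=label)

    @classmethod
    def from_files(cls, path1, path2, var_types="auto", method="rank",
                   delimiter=None):
        from .data import read_matrix

        return cls(
            read_matrix(path1, delimiter=delimiter, group_label="group1"),
            read_matrix(path2, delimiter=delimiter, group_label="group2"),
            var_types=var_types,
            method=method,
        )

    @property
    def names(self):
        return self.data1.names

    def fit(
        self,
        lambda_="aic",
        loss="F",
        rho=1.0,
        n_lambda=50,
        lambda_grid=None,
        threshold=1e-5,
        max_iter=5000,
        eps_rel=1e-4,
        path_early_stop=True,
    ):
        """Estimate the difference of the two latent precision matrices.

        lambda_='aic' tunes the constraint level over a log-spaced grid
        by minimizing (n1+n2) L(lambda) + 2 |theta|_0 with the chosen
        residual loss ('Linf', 'F', 'spectral', or 'L1'); a float fits at
        that single value.  `threshold` is the support-recovery
        hardening: entries at or below it are treated as structural
        zeros by `edges()` and `summary()`.
        """
        kw = dict(rho=rho, max_iter=max_iter, eps_rel=eps_rel)
        if isinstance(lambda_, str):
            if lambda_ != "aic":
                raise ValueError("lambda_ must be 'aic' or a number")
            grid = (np.asarray(lambda_grid, float) if lambda_grid is not None
                    else default_lambda_grid(self.problem, n_lambda=n_lambda))
            stop = None
            if path_early_stop:
                stop = make_aic_early_stop(self.corr1.matrix,
                                           self.corr2.matrix,
                                           self.data1.n, self.data2.n,
                                           loss_name=loss)
            path = solve_path(self.problem, grid, stop_when=stop, **kw)
            tuning = aic_select(path, self.corr1.matrix, self.corr2.matrix,
                                self.data1.n, self.data2.n, loss_name=loss)
            estimate = path[tuning.index_selected]
        else:
            estimate = admm_solve(self.problem, float(lambda_), **kw)
            path, tuning = [estimate], None
        return DifferentialNetworkResults(self, estimate, path, tuning,
                                          loss, threshold)


class DifferentialNetworkResults:
    """Fitted differential network.

    Attributes
    ----------
    delta : (p, p) ndarray
        Estimated difference Omega2 - Omega1 (exactly symmetric).
    lambda_ : float
        Constraint level of the reported estimate.
    tuning : TuningResult or None
        AIC trace when lambda was tuned.
    path : list of DifferenceEstimate
        The full solution path.
    """

    def __init__(self, model, estimate, path, tuning, loss, threshold):
        self.model = model
        self.estimate = estimate
        self.path = path
        self.tuning = tuning
        self.loss_name = loss
        self.threshold = threshold

    @property
    def delta(self):
        return self.estimate.delta

    @property
    def lambda_(self):
        return self.estimate.lam

    @property
    def converged(self):
        return self.estimate.converged

    @property
    def delta_thresholded(self):
        return threshold_support(self.delta, self.threshold)

    @property
    def n_edges(self):
        d = self.delta_thresholded
        return int((np.abs(np.triu(d, k=1)) > 0).sum())

    def loss(self, loss_name=None):
        """Residual-matrix norm |S1 Delta S2 - S1 + S2| of the fit."""
        return loss_value(
            self.model.corr1.matrix,
            self.model.corr2.matrix,
            self.delta,
            loss_name or self.loss_name,
        )

    def edges(self):
        """Differential edges as a DataFrame (i, j, names, delta, sign);
        sign is the direction of the conditional-dependency change."""
        names = self.model.names
        d = self.delta_thresholded
        p = d.shape[0]
        rows = [
            {
                "i": i + 1,
                "j": j + 1,
                "var_i": names[i],
                "var_j": names[j],
                "delta": d[i, j],
                "sign": "+" if d[i, j] > 0 else "-",
            }
            for i in range(p)
            for j in range(i + 1, p)
            if abs(d[i, j]) > 0
        ]
        return pd.DataFrame(rows,
                            columns=["i", "j", "var_i", "var_j", "delta", "sign"])

    def summary(self):
        """Plain-text summary of the fit."""
        m = self.model
        lines = [
            "Latent Differential Network Results",
            "=" * 46,
            f"Correlation estimator:   {m.method}",
            f"Variables:               {m.data1.p}"
            f"  ({m.data1.n_binary} binary)",
            f"Observations:            {m.data1.n} / {m.data2.n}",
            f"Lambda:                  {self.lambda_:.6g}"
            + ("  (AIC, loss=" + self.loss_name + ")" if self.tuning else ""),
            f"ADMM iterations:         {self.estimate.iterations}"
            f"  (converged: {self.converged})",
            f"Nonzero parameters:      {self.estimate.n_nonzero}",
            f"Differential edges:      {self.n_edges}"
            f"  (|delta| > {self.threshold:g})",
            f"Residual loss ({self.loss_name}):      {self.loss():.6g}",
            "=" * 46,
        ]
        edges = self.edges()
        if len(edges):
            lines.append(edges.to_string(index=False, max_rows=40))
        else:
            lines.append("(no differential edges at this threshold)")
        return "\n".join(lines)

    def plot_tuning(self, ax=None):
        """AIC versus lambda (requires matplotlib)."""
        if self.tuning is None:
            raise ValueError("fit was not tuned; nothing to plot")
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = self.tuning.table
        ax.plot(t["lam"], t["aic"], marker="o", ms=3)
        ax.axvline(self.lambda_, ls="--", color="grey")
        ax.set_xscale("log")
        ax.set_xlabel("lambda")
        ax.set_ylabel("AIC")
        return ax
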