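"""AIC-style tuning of the constraint level lambda.

The criterion is  AIC(lambda) = (n1 + n2) * L(lambda) + 2 k(lambda),
where L is a norm of the residual matrix S1 Delta(lambda) S2 - S1 + S2
(sup, Frobenius, spectral, or elementwise l1) and k is the number of
nonzero free parameters |theta|_0, counted above numerical zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["loss_value", "aic_select", "make_aic_early_stop", "TuningResult",
           "LOSSES"]

LOSSES = ("Linf", "F", "spectral", "L1")


def loss_value(s1, s2, delta_hat, loss_name="F"):
    """Norm of the residual matrix S1 Delta S2 - S1 + S2.

    loss_name: 'Linf' (max absolute entry), 'F' (Frobenius),
    'spectral' (largest singular value), or 'L1' (sum of absolute
    entries; an additional elementwise option).
    """
    s1 = np.asarray(s1, float)
    s2 = np.asarray(s2, float)
    resid = s1 @ np.asarray(delta_hat, float) @ s2 - s1 + s2
    if loss_name == "Linf":
        return float(np.abs(resid).max())
    if loss_name == "F":
        return float(np.linalg.norm(resid, "fro"))
    if loss_name == "spectral":
        return float(np.linalg.norm(resid, 2))
    if loss_name == "L1":
        return float(np.abs(resid).sum())
    raise ValueError(f"unknown loss {loss_name!r}; choose from {LOSSES}")


def make_aic_early_stop(s1, s2, n1, n2, loss_name="F", patience=6):
    """Path-truncation rule for the AIC search.

    Returns a callable for `solve_path(stop_when=...)` that stops the
    descent once the AIC of `patience` consecutive converged estimates
    has failed to improve on the running minimum.  Along these paths the
    loss flattens while the parameter count grows by hundreds per grid
    point, so once past its minimum the criterion only rises; skipping
    the dense tail saves most of the solve time without affecting the
    selected estimate.  AIC values are evaluated with `loss_name`; a
    selection with a different loss afterwards should re-run without the
    rule (the default patience is generous enough that in practice the
    sup-norm and Frobenius minima both lie inside the retained head).
    """

    def stop(estimates):
        best = np.inf
        since_best = 0
        for est in estimates:
            if est.converged:
                aic = (n1 + n2) * loss_value(s1, s2, est.delta, loss_name) \
                    + 2.0 * est.n_nonzero
                if aic < best - 1e-10:
                    best = aic
                    since_best = 0
                    continue
            # non-improving, or non-converged (which selection excludes
            # anyway): both count toward giving up on the descent
            since_best += 1
        return since_best >= patience

    return stop


@dataclass
class TuningResult:
    lambda_selected: float
    index_selected: int
    loss_name: str
    table: pd.DataFrame  # columns: lam, loss, k, aic, converged

    def __repr__(self):
        return (
            f"TuningResult(loss={self.loss_name!r}, "
            f"lambda={self.lambda_selected:.6g}, "
            f"k={int(self.table.loc[self.index_selected, 'k'])})"
        )


def aic_select(path, s1, s2, n1, n2, loss_name="F") -> TuningResult:
    """Pick lambda minimizing (n1+n2) L(lambda) + 2 |theta|_0 over a path.

    Non-converged path points are excluded; ties break toward larger
    lambda (sparser estimates).
    """
    rows = []
    for i, est in enumerate(path):
        rows.append(
            {
                "lam": est.lam,
                "loss": loss_value(s1, s2, est.delta, loss_name),
                "k": est.n_nonzero,
                "converged": est.converged,
            }
        )
    table = pd.DataFrame(rows)
    table["aic"] = (n1 + n2) * table["loss"] + 2.0 * table["k"]
    eligible = table[table["converged"]]
    if eligible.empty:
        raise RuntimeError("no converged estimates on the lambda path")
    best_aic = eligible["aic"].min()
    # ties (within numerical noise) -> largest lambda
    tied = eligible[eligible["aic"] <= best_aic + 1e-10]
    idx = int(tied["lam"].idxmax())
    return TuningResult(
        lambda_selected=float(table.loc[idx, "lam"]),
        index_selected=idx,
        loss_name=loss_name,
        table=table,
    )
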