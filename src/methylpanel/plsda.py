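"""Partial least squares discriminant analysis (PLS-DA) of methylation
descriptors.

Cases and controls are separated by PLS1 regression of a two-level coded
response (-1 = control, +1 = case) on the autoscaled mean-methylation
descriptors (one per gene x tissue); a sample is classified by the sign of
its predicted response. The percentage of correct classification is
reported under leave-one-out cross-validation by default (with a
resubstitution option), and descriptor subsets (one tissue or both) are
evaluated under the identical protocol. The first two latent-variable
scores (v1, v2) are exported for plotting.

The sign-to-class mapping is configurable: the default ``"coding"`` mapping
is consistent with the response coding (positive prediction -> case class);
the alternative ``"inverted"`` mapping assigns positive predictions to the
control class. A predicted response of exactly 0 is a tie: it is assigned
to the positive-side class of the configured mapping and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression

CONTROL_CODE = -1
CASE_CODE = +1


class PLSDAError(ValueError):
    pass


@dataclass
class PLSDAModel:
    pls: PLSRegression
    columns: list[str]
    impute_means: pd.Series
    n_components: int
    sign_mapping: str = "coding"   # "coding": positive -> case; "inverted": -> control

    def positive_class(self) -> int:
        return CASE_CODE if self.sign_mapping == "coding" else CONTROL_CODE


@dataclass
class ClassificationReport:
    table: pd.DataFrame            # sample, v1, v2, response, predicted, correct
    percent_correct: float
    n_classified: int
    n_dropped: int
    n_ties: int


def _coerce_y(y) -> np.ndarray:
    arr = np.asarray(y)
    if arr.dtype.kind in "USO":
        arr = np.where(arr == "control", CONTROL_CODE, CASE_CODE)
    arr = arr.astype(float)
    if not set(np.unique(arr)) <= {-1.0, 1.0}:
        raise PLSDAError("labels must be coded -1 (control) / +1 (case)")
    return arr


def _prepare(X: pd.DataFrame, means: pd.Series, missing: str):
    if missing == "impute":
        Xp = X.fillna(means)
        dropped = Xp.index[Xp.isna().any(axis=1)]
        Xp = Xp.drop(index=dropped)
    elif missing == "drop":
        Xp = X.dropna()
        dropped = X.index.difference(Xp.index)
    else:
        raise PLSDAError(f"unknown missing policy {missing!r}")
    return Xp, list(dropped)


def fit_plsda(
    X: pd.DataFrame,
    y,
    n_components: int = 2,
    missing: str = "impute",
    sign_mapping: str = "coding",
) -> PLSDAModel:
    """Fit PLS1 of the +/-1 response on autoscaled descriptors.

    Requires at least two samples per class; ``n_components`` may not
    exceed the rank of the centered descriptor matrix. Missing descriptor
    values are imputed by the class-agnostic descriptor mean (or the sample
    is dropped, per ``missing``).
    """
    yv = _coerce_y(y)
    if (yv == CONTROL_CODE).sum() < 2 or (yv == CASE_CODE).sum() < 2:
        raise PLSDAError("need at least two samples per class")
    means = X.mean()
    means = means[~means.isna()]
    X = X[means.index]
    Xp, dropped = _prepare(X, means, missing)
    yv = yv[[i for i, s in enumerate(X.index) if s in Xp.index]]
    rank = np.linalg.matrix_rank(Xp.to_numpy() - Xp.to_numpy().mean(axis=0))
    if n_components > rank:
        raise PLSDAError(f"n_components={n_components} exceeds rank {rank}")
    pls = PLSRegression(n_components=n_components, scale=True)
    pls.fit(Xp.to_numpy(), yv.reshape(-1, 1))
    return PLSDAModel(
        pls=pls,
        columns=list(Xp.columns),
        impute_means=means,
        n_components=n_components,
        sign_mapping=sign_mapping,
    )


def predict_response(model: PLSDAModel, X: pd.DataFrame, missing: str = "impute"):
    Xp, dropped = _prepare(X[model.columns], model.impute_means, missing)
    resp = model.pls.predict(Xp.to_numpy()).ravel() if len(Xp) else np.empty(0)
    return Xp, resp, dropped


def classify(
    model: PLSDAModel,
    X: pd.DataFrame,
    true_labels=None,
    missing: str = "impute",
) -> ClassificationReport:
    """Threshold the predicted response at 0 and report per-sample classes,
    scores on the first two PLS axes, and the percentage of correct
    classification over classified samples."""
    Xp, resp, dropped = predict_response(model, X, missing)
    pos = model.positive_class()
    predicted = np.where(resp > 0, pos, -pos)
    ties = resp == 0
    predicted[ties] = pos
    scores = model.pls.transform(Xp.to_numpy()) if len(Xp) else np.empty((0, 1))
    v1 = scores[:, 0] if scores.shape[1] >= 1 else np.full(len(Xp), np.nan)
    v2 = scores[:, 1] if scores.shape[1] >= 2 else np.full(len(Xp), np.nan)
    table = pd.DataFrame(
        {
            "sample": Xp.index,
            "v1": v1,
            "v2": v2,
            "response": resp,
            "predicted": predicted,
            "tie": ties,
        }
    )
    pct = float("nan")
    if true_labels is not None:
        yv = _coerce_y(true_labels)
        lab = pd.Series(yv, index=X.index).loc[Xp.index].to_numpy()
        table["truth"] = lab
        table["correct"] = table["predicted"] == lab
        pct = 100.0 * table["correct"].mean() if len(table) else float("nan")
    return ClassificationReport(
        table=table,
        percent_correct=pct,
        n_classified=len(table),
        n_dropped=len(dropped),
        n_ties=int(ties.sum()),
    )


def loo_percent_correct(
    X: pd.DataFrame,
    y,
    n_components: int = 2,
    missing: str = "impute",
    sign_mapping: str = "coding",
) -> float:
    """Leave-one-out cross-validated percentage of correct classification.

    Each held-out sample is predicted by a model fitted (including
    descriptor means used for imputation) on the remaining samples only.
    """
    yv = _coerce_y(y)
    correct = 0
    classified = 0
    for i in range(len(X)):
        Xtr = X.drop(index=X.index[i])
        ytr = np.delete(yv, i)
        model = fit_plsda(Xtr, ytr, n_components, missing, sign_mapping)
        Xi = X.iloc[[i]][model.columns]
        Xi = Xi.fillna(model.impute_means) if missing == "impute" else Xi.dropna()
        if Xi.isna().any().any() or len(Xi) == 0:
            continue
        resp = float(model.pls.predict(Xi.to_numpy()).ravel()[0])
        pos = model.positive_class()
        pred = pos if resp >= 0 else -pos
        classified += 1
        correct += int(pred == yv[i])
    if classified == 0:
        raise PLSDAError("no sample could be classified")
    return 100.0 * correct / classified


def evaluate_descriptor_sets(
    wide: pd.DataFrame,
    y,
    sets: dict[str, list[str]] | None = None,
    n_components: int = 2,
    cv: str = "loo",
    missing: str = "impute",
    sign_mapping: str = "coding",
) -> pd.DataFrame:
    """Run the identical fit/classify protocol on descriptor subsets.

    Default subsets are blood-only, NEC-only ('b-'/'n-' column prefixes)
    and both tissues. Reports the cross-validated (or resubstitution)
    percent correct per subset.
    """
    if sets is None:
        sets = {
            "blood": [c for c in wide.columns if c.startswith("b-")],
            "NEC": [c for c in wide.columns if c.startswith("n-")],
            "both": list(wide.columns),
        }
    rows = []
    for name, cols in sets.items():
        if not cols:
            raise PLSDAError(f"descriptor set {name!r} is empty")
        sub = wide[cols]
        if cv == "loo":
            pct = loo_percent_correct(sub, y, n_components, missing, sign_mapping)
        else:
            model = fit_plsda(sub, y, n_components, missing, sign_mapping)
            pct = classify(model, sub, y, missing).percent_correct
        rows.append({"descriptor_set": name, "n_descriptors": len(cols),
                     "percent_correct": pct, "cv": cv})
    return pd.DataFrame(rows)
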