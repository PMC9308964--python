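"""Sampled Shapley attribution of quantile predictions to covariates.

The Shapley value of covariate *i* for one prediction is its marginal
contribution averaged over all orderings in which covariates can be revealed;
exact computation is exponential in the number of covariates, so the
estimator here samples random orderings (permutation sampling): for each
sampled ordering and a background row drawn from a reference sample, walk
through the ordering replacing background values with the instance's values
and record the prediction change attributed to each covariate. Averaging over
permutations converges to the exact value and preserves local accuracy
(base value + Σ contributions = prediction) in expectation.

Land cover is treated as a single feature (its one-hot block moves as one),
so contributions are reported per physical covariate: mat, tap, elevation,
landcover.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

FEATURES = ("mat", "tap", "elevation", "landcover")


@dataclass
class AttributionResult:
    """Per-instance Shapley contributions for each percentile head.

    ``contributions``: DataFrame indexed by (instance, feature) with one
    column per percentile; ``base_values``: Series per percentile (mean
    prediction over the background sample).
    """

    contributions: pd.DataFrame
    base_values: pd.Series
    predictions: pd.DataFrame
    n_permutations: int

    def local_accuracy_gap(self) -> pd.DataFrame:
        """prediction − (base + Σ contributions) per instance and percentile."""
        total = self.contributions.groupby(level="instance").sum()
        return self.predictions - (total + self.base_values)

    def mean_abs(self) -> pd.DataFrame:
        """Mean |contribution| per feature and percentile across instances."""
        return self.contributions.abs().groupby(level="feature").mean()


def shapley_sample(
    model,
    instances: pd.DataFrame,
    background: pd.DataFrame,
    n_permutations: int = 200,
    seed: int = 0,
    features=FEATURES,
) -> AttributionResult:
    """Monte-Carlo permutation estimate of Shapley values.

    ``model`` must expose ``predict_rows`` over frames with the feature
    columns. For each instance and each sampled permutation, one background
    row supplies the values of not-yet-revealed features; all evaluation rows
    for an instance are scored in a single batched prediction call.
    """
    if len(background) == 0:
        raise ValueError("background sample must be non-empty")
    if n_permutations < 1:
        raise ValueError("need n_permutations >= 1")
    missing = [f for f in features if f not in instances.columns]
    if missing:
        raise KeyError(f"instance columns missing features: {missing}")
    rng = np.random.default_rng(seed)
    features = list(features)
    n_feat = len(features)

    base_pred = model.predict_rows(background[features]).mean(axis=0)
    percentile_cols = list(base_pred.index)

    contrib_rows = []
    preds = []
    for inst_pos in range(len(instances)):
        instance = instances.iloc[inst_pos]
        bg_idx = rng.integers(0, len(background), n_permutations)
        orders = np.argsort(rng.random((n_permutations, n_feat)), axis=1)

        # build evaluation frame: for each permutation, n_feat+1 rows walking
        # from all-background to all-instance
        eval_rows = []
        for p in range(n_permutations):
            row = background.iloc[bg_idx[p]][features].copy()
            eval_rows.append(row.copy())
            for f_idx in orders[p]:
                row[features[f_idx]] = instance[features[f_idx]]
                eval_rows.append(row.copy())
        eval_frame = pd.DataFrame(eval_rows).reset_index(drop=True)
        q = model.predict_rows(eval_frame).to_numpy()
        q = q.reshape(n_permutations, n_feat + 1, len(percentile_cols))

        deltas = np.diff(q, axis=1)  # (perm, step, percentile)
        contrib = np.zeros((n_feat, len(percentile_cols)))
        for p in range(n_permutations):
            contrib[orders[p]] += deltas[p]
        contrib /= n_permutations
        label = instances.index[inst_pos]
        for f_idx, feat in enumerate(features):
            contrib_rows.append((label, feat, *contrib[f_idx]))
        preds.append(model.predict_rows(instance.to_frame().T[features]).iloc[0])

    contributions = pd.DataFrame(
        contrib_rows, columns=["instance", "feature", *percentile_cols]
    ).set_index(["instance", "feature"])
    predictions = pd.DataFrame(preds, index=instances.index)
    return AttributionResult(
        contributions=contributions,
        base_values=base_pred,
        predictions=predictions,
        n_permutations=n_permutations,
    )


def contribution_change(result: AttributionResult, from_percentile: str = "q50",
                        to_percentile: str = "q75") -> pd.Series:
    """Percent change of mean |contribution| between two percentile heads.

    (mean|c|_to − mean|c|_from) / mean|c|_from × 100, per covariate; this is
    the normalization that lets covariate influence be compared across
    percentiles despite higher heads predicting larger values.
    """
    m = result.mean_abs()
    frm = m[from_percentile]
    if (frm == 0).any():
        raise ZeroDivisionError("zero mean contribution at the reference percentile")
    return (m[to_percentile] - frm) / frm * 100.0


def temperature_group(mat, cold: float = 10.0, warm: float = 17.5) -> np.ndarray:
    """Tag cells by the temperature regimes used in interaction summaries:
    'cold' (< 10 °C), 'intermediate' (10–17.5 °C), 'warm' (> 17.5 °C)."""
    mat = np.asarray(mat, dtype=float)
    out = np.where(mat < cold, "cold", np.where(mat < warm, "intermediate", "warm"))
    return out


def to_long_csv(result: AttributionResult, path) -> None:
    """Long-format (instance, covariate, percentile, contribution) CSV."""
    long = (
        result.contributions.stack()
        .rename("contribution")
        .rename_axis(["instance", "covariate", "percentile"])
        .reset_index()
    )
    long.to_csv(path, index=False)
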