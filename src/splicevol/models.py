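"""Splicing-code and AS-conservation classifiers.

The training protocol: keep every alternatively spliced junction and
subsample an equal number of constitutive ones (50% precision by chance),
split 60/20/20 into train/validation/test stratified by class, pick
hyperparameters by validation AUC, then refit the selected configuration
on the full dataset.  The conservation model balances conserved/lost/
gained 1:1:1 (33.3% precision by chance), repeats the whole construction
10 times with fresh subsamples, and keeps the repeat with the highest
complete-dataset AUC.

The learner is specified by contract (probabilistic scores, seeded
determinism, validation-AUC selection); the reference configuration is a
three-hidden-layer tanh feed-forward network.  Feature importance is
permutation importance (mean AUC drop).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from scipy import stats
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

ID_COLUMNS = ("junction_id", "gene_id", "pair_id", "label")


class DatasetError(ValueError):
    pass


def feature_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if c not in ID_COLUMNS]


def balance_binary(
    df: pd.DataFrame,
    seed: int = 0,
    label_col: str = "label",
    positive: str = "alternative",
) -> pd.DataFrame:
    """Keep all positive rows; subsample negatives (seeded) to equal count."""
    pos = df[df[label_col] == positive]
    neg = df[df[label_col] != positive]
    if len(pos) == 0 or len(neg) == 0:
        raise DatasetError("both classes must be non-empty")
    if len(pos) > len(neg):
        raise DatasetError(
            f"cannot balance by subsampling: {len(pos)} positive > {len(neg)} negative"
        )
    rng = np.random.default_rng(seed)
    take = rng.choice(len(neg), size=len(pos), replace=False)
    return pd.concat([pos, neg.iloc[np.sort(take)]], ignore_index=True)


def split_dataset(
    df: pd.DataFrame,
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
    label_col: str = "label",
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Stratified, disjoint, exhaustive 60/20/20 split (sizes within +-1)."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise DatasetError("fractions must sum to 1")
    if len(df) < 10:
        raise DatasetError("need at least 10 rows to split")
    rng = np.random.default_rng(seed)
    parts: list[list[pd.DataFrame]] = [[], [], []]
    for _, group in df.groupby(label_col, sort=True):
        idx = rng.permutation(len(group))
        n = len(group)
        # largest-remainder allocation so the three parts are exhaustive
        raw = [f * n for f in fractions]
        counts = [int(x) for x in raw]
        remainder = n - sum(counts)
        order = np.argsort([c - r for c, r in zip(counts, raw)])
        for i in range(remainder):
            counts[order[i]] += 1
        offset = 0
        for part, c in zip(parts, counts):
            part.append(group.iloc[idx[offset : offset + c]])
            offset += c
    out = tuple(
        pd.concat(p, ignore_index=True) if p else df.iloc[0:0] for p in parts
    )
    return out  # type: ignore[return-value]


def compute_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Rank-based AUC (ties contribute 0.5): the probability a random
    positive is scored above a random negative."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise DatasetError("both classes required to compute AUC")
    ranks = stats.rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


@dataclass
class TrainConfig:
    hidden_layer_sizes: Sequence[tuple[int, ...]] = ((16, 16, 16), (48, 48, 48))
    alphas: Sequence[float] = (1e-4, 1e-2)
    max_iter: int = 400
    # "improvement < 1% over the last 10 rounds" early-stopping analogue
    n_iter_no_change: int = 10
    tol: float = 1e-3


@dataclass
class TrainedModel:
    pipeline: Pipeline
    feature_names: list[str]
    classes: list
    config: dict
    validation_auc: float

    def predict_proba(self, df: pd.DataFrame) -> np.ndarray:
        X = df[self.feature_names].to_numpy(dtype=float)
        return self.pipeline.predict_proba(X)

    def predict(self, df: pd.DataFrame) -> np.ndarray:
        X = df[self.feature_names].to_numpy(dtype=float)
        return self.pipeline.predict(X)

    def positive_scores(self, df: pd.DataFrame, positive) -> np.ndarray:
        idx = self.classes.index(positive)
        return self.predict_proba(df)[:, idx]


@dataclass
class EvalMetrics:
    auc: float
    accuracy: float
    specificity: float
    precision: float
    p_value: float


def _check_finite(df: pd.DataFrame, cols: Sequence[str]) -> None:
    arr = df[list(cols)].to_numpy(dtype=float)
    bad = ~np.isfinite(arr)
    if bad.any():
        col = list(cols)[int(np.argwhere(bad)[0][1])]
        raise DatasetError(f"non-finite values in feature column {col!r}")


def _fit_one(
    train: pd.DataFrame,
    cols: list[str],
    label_col: str,
    hidden: tuple[int, ...],
    alpha: float,
    cfg: TrainConfig,
    seed: int,
) -> Pipeline:
    pipe = Pipeline(
        [
            ("scale", StandardScaler()),
            (
                "net",
                MLPClassifier(
                    hidden_layer_sizes=hidden,
                    activation="tanh",
                    alpha=alpha,
                    max_iter=cfg.max_iter,
                    n_iter_no_change=cfg.n_iter_no_change,
                    tol=cfg.tol,
                    random_state=seed,
                ),
            ),
        ]
    )
    X = train[cols].to_numpy(dtype=float)
    y = train[label_col].to_numpy()
    import warnings

    with warnings.catch_warnings():
        from sklearn.exceptions import ConvergenceWarning

        warnings.simplefilter("ignore", ConvergenceWarning)
        pipe.fit(X, y)
    return pipe


def model_auc(model: TrainedModel, df: pd.DataFrame, label_col: str = "label") -> float:
    """Binary AUC, or macro-averaged one-vs-rest AUC for >2 classes."""
    proba = model.predict_proba(df)
    y = df[label_col].to_numpy()
    aucs = []
    for i, cls in enumerate(model.classes):
        binary = (y == cls).astype(int)
        if binary.sum() in (0, len(binary)):
            continue
        aucs.append(compute_auc(proba[:, i], binary))
    if not aucs:
        raise DatasetError("no class present in both states")
    if len(model.classes) == 2:
        return aucs[-1] if len(aucs) == 1 else float(np.mean(aucs))
    return float(np.mean(aucs))


def train_classifier(
    train: pd.DataFrame,
    validation: pd.DataFrame,
    config: Optional[TrainConfig] = None,
    seed: int = 0,
    label_col: str = "label",
) -> TrainedModel:
    """Grid-select hyperparameters by validation AUC, then refit the chosen
    configuration on train+validation (the paper refits on the full data)."""
    cfg = config or TrainConfig()
    cols = feature_columns(train)
    _check_finite(train, cols)
    _check_finite(validation, cols)
    classes = sorted(pd.unique(pd.concat([train[label_col], validation[label_col]])))
    best = None
    for hidden in cfg.hidden_layer_sizes:
        for alpha in cfg.alphas:
            pipe = _fit_one(train, cols, label_col, tuple(hidden), alpha, cfg, seed)
            tmp = TrainedModel(
                pipeline=pipe,
                feature_names=cols,
                classes=list(pipe.named_steps["net"].classes_),
                config={"hidden": tuple(hidden), "alpha": alpha},
                validation_auc=float("nan"),
            )
            auc = model_auc(tmp, validation, label_col)
            if best is None or auc > best[0]:
                best = (auc, tuple(hidden), alpha)
    assert best is not None
    val_auc, hidden, alpha = best
    full = pd.concat([train, validation], ignore_index=True)
    pipe = _fit_one(full, cols, label_col, hidden, alpha, cfg, seed)
    return TrainedModel(
        pipeline=pipe,
        feature_names=cols,
        classes=list(pipe.named_steps["net"].classes_),
        config={"hidden": hidden, "alpha": alpha},
        validation_auc=val_auc,
    )


def evaluate_binary(
    model: TrainedModel,
    test: pd.DataFrame,
    positive: str = "alternative",
    label_col: str = "label",
) -> EvalMetrics:
    y = (test[label_col].to_numpy() == positive).astype(int)
    scores = model.positive_scores(test, positive)
    pred = (scores >= 0.5).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    auc = compute_auc(scores, y)
    pos_scores, neg_scores = scores[y == 1], scores[y == 0]
    p = float(stats.mannwhitneyu(pos_scores, neg_scores, alternative="two-sided").pvalue)
    return EvalMetrics(
        auc=auc,
        accuracy=(tp + tn) / len(y),
        specificity=tn / (tn + fp) if (tn + fp) else float("nan"),
        precision=tp / (tp + fp) if (tp + fp) else float("nan"),
        p_value=p,
    )


def variable_importance(
    model: TrainedModel,
    dataset: pd.DataFrame,
    seed: int = 0,
    n_repeats: int = 20,
    label_col: str = "label",
) -> pd.DataFrame:
    """Permutation importance: mean AUC drop over ``n_repeats`` shuffles of
    each feature column, ranked descending."""
    rng = np.random.default_rng(seed)
    baseline = model_auc(model, dataset, label_col)
    rows = []
    for col in model.feature_names:
        drops = []
        for _ in range(n_repeats):
            shuffled = dataset.copy()
            shuffled[col] = rng.permutation(shuffled[col].to_numpy())
            drops.append(baseline - model_auc(model, shuffled, label_col))
        rows.append({"feature": col, "importance": float(np.mean(drops))})
    out = pd.DataFrame(rows).sort_values(
        "importance", ascending=False, kind="stable"
    )
    out["rank"] = range(1, len(out) + 1)
    return out.reset_index(drop=True)


@dataclass
class ConservationFit:
    best_model: TrainedModel
    best_auc: float
    repeat_aucs: list[float] = field(default_factory=list)
    best_repeat: int = -1


def fit_conservation_model(
    pairs: pd.DataFrame,
    repeats: int = 10,
    seed: int = 0,
    config: Optional[TrainConfig] = None,
    label_col: str = "label",
    min_rows_per_class: int = 10,
) -> ConservationFit:
    """1:1:1-balanced conservation model, best of ``repeats`` reseeded runs.

    Each repeat subsamples every class down to the smallest class size,
    splits 60/20/20, trains, and is scored by AUC on the complete dataset;
    the repeat with the highest complete-dataset AUC wins.
    """
    counts = pairs[label_col].value_counts()
    for cls, n in counts.items():
        if n < min_rows_per_class:
            raise DatasetError(f"class {cls!r} has only {n} rows (< {min_rows_per_class})")
    n_min = int(counts.min())
    fit = ConservationFit(best_model=None, best_auc=-1.0)  # type: ignore[arg-type]
    for r in range(repeats):
        rng = np.random.default_rng((seed, r))
        sampled = []
        for _, group in pairs.groupby(label_col, sort=True):
            take = rng.choice(len(group), size=n_min, replace=False)
            sampled.append(group.iloc[np.sort(take)])
        balanced = pd.concat(sampled, ignore_index=True)
        train, val, _test = split_dataset(balanced, seed=seed + r, label_col=label_col)
        model = train_classifier(train, val, config=config, seed=seed + r, label_col=label_col)
        auc = model_auc(model, pairs, label_col)
        fit.repeat_aucs.append(auc)
        if auc > fit.best_auc:
            fit.best_auc = auc
            fit.best_model = model
            fit.best_repeat = r
    return fit


# ---------------------------------------------------------------------------
# conservation features


def similarity_from_counts(
    alignment_length: int, gaps: int, mismatches: int, total_length: int
) -> float:
    """(alignment length - gaps - mismatches) / total length."""
    return (alignment_length - gaps - mismatches) / total_length


def flank_similarity(seq_a: str, seq_b: str) -> float:
    """Similarity of two flank sequences from a global pairwise alignment.

    Identical sequences score 1.0; substitutions and gaps reduce the value
    per the counting formula above (total length = alignment length).
    """
    if not seq_a or not seq_b:
        return 0.0
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -1
    aligner.open_gap_score = -3
    aligner.extend_gap_score = -1
    aln = aligner.align(seq_a.upper(), seq_b.upper())[0]
    a_str, b_str = str(aln[0]), str(aln[1])
    length = len(a_str)
    gaps = sum(1 for x, y in zip(a_str, b_str) if x == "-" or y == "-")
    mismatches = sum(
        1 for x, y in zip(a_str, b_str) if x != "-" and y != "-" and x != y
    )
    return similarity_from_counts(length, gaps, mismatches, length)


_DIFF_EXCLUDE = {"label"}


def build_conservation_dataset(
    rows_a: pd.DataFrame,
    rows_b: pd.DataFrame,
    pairs: Sequence[tuple[str, str, str]],
    flanks_a: Optional[dict[str, str]] = None,
    flanks_b: Optional[dict[str, str]] = None,
    extra: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Per-ortholog-pair feature differences for the conservation model.

    ``pairs`` holds (junction_id_a, junction_id_b, label) with label in
    {conserved, lost, gained}.  Numeric feature differences are B minus A;
    flank similarity is added when flank sequences are supplied; ``extra``
    (indexed like the output) can carry precomputed columns such as a
    TE-insertion flag or copy-number change.
    """
    a = rows_a.set_index("junction_id")
    b = rows_b.set_index("junction_id")
    numeric = [
        c
        for c in a.columns
        if c not in ID_COLUMNS and c in b.columns and pd.api.types.is_numeric_dtype(a[c])
    ]
    out_rows = []
    for ja, jb, label in pairs:
        if ja not in a.index or jb not in b.index:
            continue
        row = {"pair_id": f"{ja}|{jb}", "label": label}
        for c in numeric:
            row[f"delta_{c}"] = float(b.loc[jb, c]) - float(a.loc[ja, c])
        if flanks_a is not None and flanks_b is not None:
            row["flank_similarity"] = flank_similarity(
                flanks_a.get(ja, ""), flanks_b.get(jb, "")
            )
        out_rows.append(row)
    df = pd.DataFrame(out_rows)
    if extra is not None and len(df):
        df = df.merge(extra, on="pair_id", how="left")
    return df
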