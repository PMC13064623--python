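"""Cross-validation harness and within-subject statistics.

The evaluation protocol treats each image pair as a subject measured once
under every model (a fully crossed within-subject design): 5-fold
cross-validation produces per-image metric tables, a one-way
repeated-measures ANOVA tests for a model main effect per metric, and
Holm-adjusted paired t-tests localize which model pairs differ.

The ANOVA is the classical within-subjects decomposition:

    F = MS_model / MS_(model x subject),
    df = (m - 1), (m - 1)(n - 1)

computed in closed form (no sphericity correction by default, matching
the protocol; Greenhouse-Geisser is available as an option).
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import KFold
from statsmodels.stats.multitest import multipletests

from .imagecore import ImageDataset
from .generators import translate
from .metrics import metric_report

__all__ = [
    "FoldResult",
    "ModelComparison",
    "kfold_split",
    "evaluate_model",
    "rm_anova",
    "holm_pairwise",
    "cross_validate",
]

METRIC_COLUMNS = ("ssim", "psnr_db", "npsnr", "frc_resolution_px", "hf_disagreement")


@dataclass
class FoldResult:
    fold_index: int
    per_image: pd.DataFrame  # one row per validation image
    summary: pd.DataFrame    # mean/sd per metric


@dataclass
class ModelComparison:
    metric_name: str
    f_stat: float
    p_value: float
    pairwise: pd.DataFrame  # Holm-adjusted p, models x models


def kfold_split(n: int, k: int = 5, seed: int = 0) -> np.ndarray:
    """Random partition of ``n`` items into ``k`` folds with sizes
    differing by at most one; returns the fold index of each item."""
    if n < k or k < 2:
        raise ValueError("need n >= k >= 2")
    fold_of = np.empty(n, dtype=int)
    for f, (_, val) in enumerate(
        KFold(n_splits=k, shuffle=True, random_state=seed).split(np.arange(n))
    ):
        fold_of[val] = f
    return fold_of


def evaluate_model(
    generator, validation, fold_index: int = 0,
    translate_fn: Optional[Callable] = None,
) -> FoldResult:
    """Score a generator on held-out pairs.

    Each row holds the full-reference metrics of the translated source
    against the target plus the untranslated confocal baseline
    (``baseline_*`` columns) for the same pair.
    """
    pairs = list(validation)
    if not pairs:
        raise ValueError("empty validation set")
    tf = translate_fn or (lambda img: translate(generator, img))
    rows = []
    for s in pairs:
        gen = tf(s.source)
        rep = metric_report(gen.pixels, s.target.pixels)
        base = metric_report(s.source.pixels, s.target.pixels)
        row = {"sample_id": s.sample_id}
        for k, v in rep.__dict__.items():
            if v is not None:
                row[k] = v
        for k, v in base.__dict__.items():
            if v is not None:
                row[f"baseline_{k}"] = v
        rows.append(row)
    per_image = pd.DataFrame(rows)
    num = per_image.drop(columns=["sample_id"])
    summary = pd.DataFrame({"mean": num.mean(), "sd": num.std(ddof=1)})
    return FoldResult(fold_index=fold_index, per_image=per_image, summary=summary)


def rm_anova(matrix: np.ndarray) -> Tuple[float, float]:
    """One-way repeated-measures ANOVA on a subjects x models matrix.

    Returns ``(F, p)``.  Degenerate cases: zero model *and* error variance
    gives (0, 1); a perfectly consistent model effect (zero error
    variance, nonzero effect) gives (inf, 0).
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2 or m.shape[0] < 3:
        raise ValueError("need >= 3 subjects and >= 2 models")
    if not np.all(np.isfinite(m)):
        raise ValueError("missing or non-finite cells")
    n, k = m.shape
    grand = m.mean()
    ss_model = n * np.sum((m.mean(axis=0) - grand) ** 2)
    ss_subj = k * np.sum((m.mean(axis=1) - grand) ** 2)
    ss_total = np.sum((m - grand) ** 2)
    ss_err = ss_total - ss_model - ss_subj
    df_model = k - 1
    df_err = (k - 1) * (n - 1)
    ms_model = ss_model / df_model
    ms_err = max(ss_err, 0.0) / df_err
    if ms_err <= np.finfo(float).eps * max(1.0, abs(grand)) ** 2:
        if ms_model <= np.finfo(float).eps:
            return 0.0, 1.0
        return float("inf"), 0.0
    f = ms_model / ms_err
    p = float(stats.f.sf(f, df_model, df_err))
    return float(f), p


def holm_pairwise(matrix: np.ndarray,
                  labels: Optional[Sequence] = None) -> pd.DataFrame:
    """All-pairs paired t-tests with Holm step-down adjustment.

    Returns a symmetric models x models DataFrame of adjusted p-values
    (diagonal NaN).  Identical columns give p = 1.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2 or m.shape[0] < 3:
        raise ValueError("need >= 3 subjects and >= 2 models")
    k = m.shape[1]
    labels = list(labels) if labels is not None else list(range(1, k + 1))
    pairs = list(itertools.combinations(range(k), 2))
    raw = []
    for i, j in pairs:
        d = m[:, i] - m[:, j]
        if np.allclose(d, d[0]):
            raw.append(1.0 if np.allclose(d, 0) else 0.0)
        else:
            raw.append(float(stats.ttest_rel(m[:, i], m[:, j]).pvalue))
    adj = multipletests(raw, method="holm")[1] if pairs else []
    out = pd.DataFrame(np.full((k, k), np.nan), index=labels, columns=labels)
    for (i, j), p in zip(pairs, adj):
        out.iat[i, j] = out.iat[j, i] = p
    return out


def _gg_epsilon(m: np.ndarray) -> float:
    """Greenhouse-Geisser sphericity epsilon (optional correction)."""
    centered = m - m.mean(axis=0)
    s = np.cov(centered.T)
    k = s.shape[0]
    mean_diag = np.trace(s) / k
    num = (k * (mean_diag - s.mean())) ** 2
    den = (k - 1) * (np.sum(s**2) - 2 * k * np.sum(s.mean(axis=1) ** 2)
                     + k**2 * s.mean() ** 2)
    return float(num / den) if den > 0 else 1.0


def rm_anova_gg(matrix: np.ndarray) -> Tuple[float, float, float]:
    """Repeated-measures ANOVA with Greenhouse-Geisser-corrected p."""
    m = np.asarray(matrix, dtype=float)
    f, _ = rm_anova(m)
    n, k = m.shape
    eps = _gg_epsilon(m)
    p = float(stats.f.sf(f, eps * (k - 1), eps * (k - 1) * (n - 1)))
    return f, p, eps


def cross_validate(
    dataset: ImageDataset,
    model_specs: Dict,
    train_fn: Callable,
    k: int = 5,
    seed: int = 0,
    metrics: Sequence[str] = ("ssim", "psnr_db"),
) -> Tuple[Dict, List[ModelComparison]]:
    """Full protocol: per fold and model, reseed, train on k-1 folds,
    evaluate on the held-out fold; pool per-image metrics across folds and
    compare models with rm-ANOVA + Holm pairwise tests.

    ``train_fn(train_subset, spec, fold_seed) -> generator`` encapsulates
    the framework (Pix2Pix or CycleGAN) and its configuration.

    Returns ``({model: [FoldResult...]}, [ModelComparison...])``.
    """
    from .adversarial import seed_all

    n = len(dataset)
    fold_of = kfold_split(n, k=k, seed=seed)
    for s, f in zip(dataset.samples, fold_of):
        dataset.fold_of[s.sample_id] = int(f)
    fold_results: Dict = {name: [] for name in model_specs}
    for name, spec in model_specs.items():
        for fold in range(k):
            name_key = zlib.crc32(str(name).encode()) % 2**31
            fold_seed = int(
                np.random.SeedSequence([seed, fold, name_key]).generate_state(1)[0]
                % 2**31
            )
            seed_all(fold_seed)
            train_ids = [s.sample_id for s, f in zip(dataset.samples, fold_of) if f != fold]
            val_ids = [s.sample_id for s, f in zip(dataset.samples, fold_of) if f == fold]
            gen = train_fn(dataset.subset(train_ids), spec, fold_seed)
            fr = evaluate_model(gen, dataset.subset(val_ids), fold_index=fold)
            fold_results[name].append(fr)
    comparisons = []
    names = list(model_specs)
    pooled = {
        name: pd.concat([fr.per_image for fr in frs]).set_index("sample_id").sort_index()
        for name, frs in fold_results.items()
    }
    for metric in metrics:
        mat = np.column_stack([pooled[name][metric].to_numpy() for name in names])
        f, p = rm_anova(mat)
        pw = holm_pairwise(mat, labels=names)
        comparisons.append(ModelComparison(metric_name=metric, f_stat=f,
                                           p_value=p, pairwise=pw))
    return fold_results, comparisons
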