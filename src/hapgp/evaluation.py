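"""Cross-validated assessment of prediction accuracy and bias.

Fivefold cross-validation, replicated twenty times with a fresh random
fold layout each replicate.  Within a replicate, every fold serves once as
the validation set: its phenotypes are masked, variance components are
re-estimated by REML on the remaining four folds, and direct genomic
values (DGVs) are predicted for the masked individuals.  The five folds'
predictions are pooled, giving one accuracy and one bias slope per
replicate:

* accuracy = cor(DGV, y_adj) / sqrt(h2), with h2 the full-data REML
  estimate for the kernel (the role the heritability table plays in the
  study design);
* bias = OLS slope of y_adj on DGV; 1 is unbiased, > 1 indicates
  deflation and < 1 inflation of the DGVs.  Across replicates, a
  one-sample t-test of the mean slope against 1 flags significant bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .kernels import Kernel
from .mixed_model import VarianceComponents, predict_dgv, reml_single_kernel

DEFAULT_FOLDS = 5
DEFAULT_REPLICATES = 20
BIAS_ALPHA = 0.05


@dataclass
class CVLayout:
    replicate: int
    fold: np.ndarray  # individual -> fold index in {0..k-1}
    seed: int

    @property
    def n_folds(self) -> int:
        return int(self.fold.max()) + 1


@dataclass
class CVResult:
    accuracy: np.ndarray          # per replicate
    bias: np.ndarray              # per replicate
    h2: float                     # denominator used for accuracy
    bias_pvalue: float
    per_fold_accuracy: list[np.ndarray] = field(default_factory=list)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.accuracy))

    @property
    def sd_accuracy(self) -> float:
        return float(np.std(self.accuracy, ddof=1))

    @property
    def mean_bias(self) -> float:
        return float(np.mean(self.bias))

    @property
    def sd_bias(self) -> float:
        return float(np.std(self.bias, ddof=1))

    @property
    def bias_significant(self) -> bool:
        return bool(self.bias_pvalue < BIAS_ALPHA)


def make_cv_layouts(n: int, k: int = DEFAULT_FOLDS,
                    reps: int = DEFAULT_REPLICATES,
                    seed: int = 0) -> list[CVLayout]:
    """Random fold layouts: a permutation chunked into k near-equal folds.

    Fold sizes differ by at most one; the first ``n % k`` folds take the
    extra individual.  Deterministic given the seed; each replicate draws
    a fresh permutation.
    """
    if n < k:
        raise ValueError(f"cannot split {n} individuals into {k} folds")
    rng = np.random.default_rng(seed)
    sizes = np.full(k, n // k, dtype=np.int64)
    sizes[: n % k] += 1
    layouts = []
    for rep in range(reps):
        perm = rng.permutation(n)
        fold = np.empty(n, dtype=np.int64)
        start = 0
        for f, size in enumerate(sizes):
            fold[perm[start:start + size]] = f
            start += size
        layouts.append(CVLayout(rep, fold, seed))
    return layouts


def accuracy(dgv: np.ndarray, y_adj: np.ndarray, h2: float) -> float:
    """Validation accuracy: cor(DGV, adjusted phenotype) / sqrt(h2)."""
    if not 0 < h2 <= 1:
        raise ValueError(f"h2 must lie in (0, 1], got {h2}")
    dgv = np.asarray(dgv, dtype=np.float64)
    y_adj = np.asarray(y_adj, dtype=np.float64)
    if len(dgv) < 3:
        raise ValueError("need at least 3 validation individuals")
    if np.std(dgv) == 0 or np.std(y_adj) == 0:
        raise ValueError("zero variance in DGV or phenotype: accuracy undefined")
    r = float(np.corrcoef(dgv, y_adj)[0, 1])
    return r / float(np.sqrt(h2))


def bias_slope(y_adj: np.ndarray, dgv: np.ndarray) -> float:
    """OLS regression slope of the adjusted phenotype on the DGV."""
    dgv = np.asarray(dgv, dtype=np.float64)
    y_adj = np.asarray(y_adj, dtype=np.float64)
    if len(dgv) < 3:
        raise ValueError("need at least 3 validation individuals")
    if np.std(dgv) == 0:
        raise ValueError("zero DGV variance: slope undefined")
    return float(stats.linregress(dgv, y_adj).slope)


def bias_regression(slopes: np.ndarray) -> tuple[float, float, float, bool]:
    """Across-replicate bias summary: (mean, se, p-value, significant).

    Two-sided one-sample t-test of the mean slope against 1 at alpha 0.05.
    """
    slopes = np.asarray(slopes, dtype=np.float64)
    t = stats.ttest_1samp(slopes, popmean=1.0)
    se = float(np.std(slopes, ddof=1) / np.sqrt(len(slopes)))
    return float(np.mean(slopes)), se, float(t.pvalue), bool(t.pvalue < BIAS_ALPHA)


def run_cv(y_adj: np.ndarray, kernel: Kernel, layouts: list[CVLayout],
           h2: float | None = None,
           individuals: list[str] | None = None) -> CVResult:
    """Full cross-validation for one kernel.

    Variance components are re-estimated on each training portion; the h2
    used in the accuracy denominator is the full-data REML estimate for
    this kernel unless supplied.  Per-replicate accuracies pool all five
    folds' validation predictions; per-fold accuracies are kept for
    diagnostics.
    """
    y_adj = np.asarray(y_adj, dtype=np.float64)
    n = len(y_adj)
    if kernel.n != n:
        raise ValueError("kernel does not cover all phenotyped individuals")
    if h2 is None:
        h2 = reml_single_kernel(y_adj, kernel).h2
    accs, biases, per_fold = [], [], []
    for layout in layouts:
        dgv_pool = np.empty(n)
        fold_accs = []
        for f in range(layout.n_folds):
            val = np.where(layout.fold == f)[0]
            train = np.where(layout.fold != f)[0]
            try:
                vc = reml_single_kernel(y_adj[train], _subkernel(kernel, train))
                pred = predict_dgv(y_adj[train], train, kernel, vc)
            except ValueError as exc:
                raise ValueError(
                    f"replicate {layout.replicate}, fold {f}: {exc}"
                ) from exc
            dgv_pool[val] = pred.dgv[val]
            if len(val) >= 3 and np.std(pred.dgv[val]) > 0:
                fold_accs.append(accuracy(pred.dgv[val], y_adj[val], h2))
        accs.append(accuracy(dgv_pool, y_adj, h2))
        biases.append(bias_slope(y_adj, dgv_pool))
        per_fold.append(np.asarray(fold_accs))
    accs = np.asarray(accs)
    biases = np.asarray(biases)
    _, _, pval, _ = bias_regression(biases)
    return CVResult(accs, biases, float(h2), pval, per_fold)


def _subkernel(k: Kernel, idx: np.ndarray) -> Kernel:
    return Kernel(k.matrix[np.ix_(idx, idx)], k.model, k.denominator, k.class_tag)


def results_table(results: dict[tuple[str, str, str], CVResult]):
    """Summary frame keyed by (trait, class, model), one row each."""
    import pandas as pd

    rows = []
    for (trait, cls, model), r in results.items():
        rows.append({
            "trait": trait, "class": cls, "model": model,
            "mean_accuracy": r.mean_accuracy, "sd_accuracy": r.sd_accuracy,
            "mean_bias": r.mean_bias, "sd_bias": r.sd_bias,
            "bias_significant": r.bias_significant,
        })
    return pd.DataFrame(rows)
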