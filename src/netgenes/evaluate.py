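"""Model evaluation: rank-based AUROC, leave-one-species-out validation,
and paired comparison of two essentiality-label versions.

LOSO (leave-one-species-out) holds out one organism's genes entirely,
trains the undersampled-forest ensemble on all remaining organisms, and
scores the held-out organism — the relevant notion of generalization when
the model is meant to be applied to organisms it has never seen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import model as model_mod
from .io import Interactome, LabelSet
from .model import ModelConfig

logger = logging.getLogger("netgenes")


def auroc(scores, labels) -> float:
    """Area under the ROC curve via the rank (Mann–Whitney) statistic.

    Midranks handle ties, so the result equals
    ``P(score_pos > score_neg) + 0.5 * P(score_pos == score_neg)`` for a
    random positive/negative pair.

    Raises ``ValueError`` when only one class is present (AUROC undefined).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUROC undefined: labels contain a single class")
    ranks = stats.rankdata(scores)  # midranks
    rank_sum_pos = ranks[labels == 1].sum()
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


@dataclass
class LosoResult:
    per_organism: dict[str, float]
    records: pd.DataFrame  # organism, auroc, n_pos, n_neg, version_tag
    version_tag: str
    config: ModelConfig
    trained_on: dict[str, list[str]]
    n_skipped: int = 0

    @property
    def mean_auroc(self) -> float:
        return float(np.mean(list(self.per_organism.values())))

    def to_csv(self, path: str | Path) -> None:
        self.records.to_csv(path, index=False)


def loso(
    cohort: list[tuple[Interactome, pd.DataFrame, LabelSet]],
    cfg: ModelConfig | None = None,
    allow_nonstandard_schema: bool = False,
) -> LosoResult:
    """Leave-one-species-out evaluation over an organism cohort.

    Organisms whose labels contain a single class are skipped with a
    warning and excluded from the mean rather than imputed.
    """
    cfg = cfg or ModelConfig()
    if len(cohort) < 2:
        raise ValueError("LOSO requires at least two organisms")
    schemas = {tuple(fm.columns) for _, fm, _ in cohort}
    if len(schemas) != 1:
        raise ValueError("all cohort feature matrices must share one schema")
    version_tags = {lbl.version_tag for _, _, lbl in cohort}
    per_organism: dict[str, float] = {}
    trained_on: dict[str, list[str]] = {}
    rows = []
    n_skipped = 0
    for i, (net, fm, lbl) in enumerate(cohort):
        if not lbl.essential or not lbl.non_essential:
            logger.warning("LOSO: skipping %s (single-class labels)", lbl.organism)
            n_skipped += 1
            continue
        train_items = [c for j, c in enumerate(cohort) if j != i]
        train_fm = pd.concat([c[1] for c in train_items], axis=0)
        train_labels = LabelSet(
            organism="+".join(c[2].organism for c in train_items),
            essential=set().union(*(c[2].essential for c in train_items)),
            universe=set().union(*(c[2].universe for c in train_items)),
            version_tag=lbl.version_tag,
        )
        ens = model_mod.train(
            train_fm, train_labels, cfg, allow_nonstandard_schema=allow_nonstandard_schema
        )
        ens.organisms = [c[2].organism for c in train_items]
        test_genes = sorted(lbl.universe)
        probs = ens.predict_proba(fm.loc[test_genes])
        y = np.array([1 if g in lbl.essential else 0 for g in test_genes])
        score = auroc(probs.to_numpy(), y)
        per_organism[lbl.organism] = score
        trained_on[lbl.organism] = ens.organisms
        rows.append(
            {
                "organism": lbl.organism,
                "auroc": score,
                "n_pos": len(lbl.essential),
                "n_neg": len(lbl.non_essential),
                "version_tag": lbl.version_tag,
            }
        )
        logger.info("LOSO %s: AUROC %.3f", lbl.organism, score)
    return LosoResult(
        per_organism=per_organism,
        records=pd.DataFrame(rows),
        version_tag="/".join(sorted(version_tags)),
        config=cfg,
        trained_on=trained_on,
        n_skipped=n_skipped,
    )


@dataclass
class ComparisonReport:
    per_organism_diff: dict[str, float]  # B - A
    mean_diff: float
    mean_diff_percent: int
    paired_t: float
    paired_p: float
    welch_t: float
    welch_p: float
    degenerate: bool  # zero-variance differences: paired test undefined

    def summary(self) -> str:
        lines = [
            f"mean AUROC difference: {self.mean_diff:+.4f} "
            f"({self.mean_diff_percent:+d}% rounded)",
        ]
        if self.degenerate:
            lines.append("paired t-test degenerate (zero-variance differences)")
        else:
            lines.append(f"paired t-test: t={self.paired_t:.3f}, p={self.paired_p:.3f}")
        lines.append(f"Welch t-test: t={self.welch_t:.3f}, p={self.welch_p:.3f}")
        return "\n".join(lines)


def compare_label_versions(res_a: LosoResult, res_b: LosoResult) -> ComparisonReport:
    """Paired comparison of per-organism AUROCs between two label versions.

    Both a paired t-test and a Welch two-sample t-test are reported; with
    zero-variance differences the paired test is flagged degenerate instead
    of producing a spurious p-value.
    """
    orgs_a, orgs_b = set(res_a.per_organism), set(res_b.per_organism)
    if orgs_a != orgs_b:
        raise ValueError(
            f"organism sets differ: {sorted(orgs_a.symmetric_difference(orgs_b))[:10]}"
        )
    orgs = sorted(orgs_a)
    a = np.array([res_a.per_organism[o] for o in orgs])
    b = np.array([res_b.per_organism[o] for o in orgs])
    diffs = b - a
    mean_diff = float(diffs.mean())
    degenerate = bool(np.allclose(diffs, diffs[0]))
    if degenerate:
        paired_t, paired_p = np.nan, np.nan
    else:
        paired = stats.ttest_rel(b, a)
        paired_t, paired_p = float(paired.statistic), float(paired.pvalue)
    welch = stats.ttest_ind(b, a, equal_var=False)
    return ComparisonReport(
        per_organism_diff=dict(zip(orgs, diffs)),
        mean_diff=mean_diff,
        mean_diff_percent=int(round(mean_diff * 100)),
        paired_t=paired_t,
        paired_p=paired_p,
        welch_t=float(welch.statistic),
        welch_p=float(welch.pvalue),
        degenerate=degenerate,
    )


def load_reference_scores() -> pd.DataFrame:
    """Published per-organism LOSO AUROCs for the 27-organism training cohort
    plus 7 additional held-out organisms, under both label versions (DEG10,
    DEG15).  ``training_cohort`` marks the 27 organisms the deployed model
    was trained on.
    """
    with resources.files("netgenes.data").joinpath("loso_reference.csv").open() as fh:
        return pd.read_csv(fh)
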