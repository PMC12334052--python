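"""Virtual-screening validation: hit ranking and ROC/AUC over actives/decoys.

Scores follow the "higher is better" convention of empirical docking scoring
functions.  The AUC equals the probability that a randomly chosen active
outscores a randomly chosen decoy, with ties counted half — the normalised
Mann–Whitney U statistic.  0.5 means no discrimination; ≥0.7 is the usual
bar for acceptable enrichment; 1.0 is perfect separation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn import metrics as _skm


@dataclass
class ScoredCompoundSet:
    """Scored, optionally binary-labelled compounds (active=1, decoy=0)."""

    ids: np.ndarray
    scores: np.ndarray
    labels: np.ndarray | None = None  # 1 = active, 0 = decoy

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.ids) != len(set(self.ids)):
            raise ValueError("compound ids must be unique")
        if not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite (no NaN/inf)")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != self.scores.shape:
                raise ValueError("labels must match scores in length")
            if not np.isin(self.labels, (0, 1)).all():
                raise ValueError("labels must be 0 (decoy) or 1 (active)")

    def __len__(self) -> int:
        return len(self.ids)

    def _require_both_classes(self) -> np.ndarray:
        if self.labels is None:
            raise ValueError("compound set has no labels")
        if len(np.unique(self.labels)) < 2:
            raise ValueError("both actives and decoys are required")
        return self.labels

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ScoredCompoundSet":
        """Read an ``id<TAB>score[<TAB>label]`` table (header optional).

        Labels may be 0/1 or the strings ``active``/``decoy``.
        """
        df = pd.read_csv(path, sep="\t")
        if df.columns[0].lower() not in ("id", "compound_id", "compound"):
            df = pd.read_csv(path, sep="\t", header=None)
            df.columns = ["id", "score", "label"][: df.shape[1]]
        labels = None
        if df.shape[1] >= 3:
            raw = df.iloc[:, 2]
            if raw.dtype == object:
                mapping = {"active": 1, "decoy": 0}
                raw = raw.str.lower().map(mapping)
                if raw.isna().any():
                    raise ValueError("labels must be active/decoy or 0/1")
            labels = raw.to_numpy()
        return cls(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy(), labels)

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame({"id": self.ids, "score": self.scores})
        if self.labels is not None:
            df["label"] = np.where(self.labels == 1, "active", "decoy")
        df.to_csv(path, sep="\t", index=False)


def count_above_reference(compounds: ScoredCompoundSet, reference_score: float) -> int:
    """Number of compounds scoring strictly above a reference (native) ligand."""
    return int(np.sum(compounds.scores > reference_score))


def roc_points(compounds: ScoredCompoundSet) -> np.ndarray:
    """ROC curve as ordered ``(fpr, tpr)`` pairs from (0, 0) to (1, 1).

    Thresholds sweep the scores in descending order with tied scores grouped
    at a single threshold, so total ties yield the chance diagonal.
    """
    labels = compounds._require_both_classes()
    fpr, tpr, _ = _skm.roc_curve(labels, compounds.scores, drop_intermediate=False)
    return np.column_stack([fpr, tpr])


def auc(compounds: ScoredCompoundSet) -> float:
    """Area under the ROC curve (trapezoidal; ties credited half)."""
    labels = compounds._require_both_classes()
    return float(_skm.roc_auc_score(labels, compounds.scores))
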