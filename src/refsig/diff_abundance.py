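"""Standardized differential-abundance summaries and heat-map export.

Selected ASV columns are standardized to zero mean and unit variance over
all samples; the case/control difference of standardized group means gives
each feature its direction label ("ASD increased" when cases are higher).
Structural absence — zero raw counts in every sample of one group — is
flagged separately, since a standardized mean cannot distinguish "rare"
from "never observed".
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .core_io import AsvTable
from .refs import zscore_normalize

__all__ = ["AbundanceSummary", "FeatureSummary", "differential_abundance", "export_heatmap"]


@dataclass
class FeatureSummary:
    asv_id: str
    mean_case: float  # standardized scale
    mean_control: float
    direction: str  # "ASD increased" | "ASD decreased" | "tied"
    absent_in_case: bool
    absent_in_control: bool


@dataclass
class AbundanceSummary:
    features: dict[str, FeatureSummary]
    standardized: pd.DataFrame  # samples x features, signature order

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "asv_id": f.asv_id,
                    "mean_case": f.mean_case,
                    "mean_control": f.mean_control,
                    "direction": f.direction,
                    "absent_in_case": f.absent_in_case,
                    "absent_in_control": f.absent_in_control,
                }
                for f in self.features.values()
            ]
        )


def differential_abundance(
    table: AsvTable, feature_ids: Sequence[str]
) -> AbundanceSummary:
    """Standardized group means, direction labels and absence flags.

    ``feature_ids`` fixes the column order of the standardized matrix
    (signature importance rank when called on a selected signature).
    """
    feature_ids = list(feature_ids)
    sub = table.subset_asvs(feature_ids)
    y = sub.label_vector().values.astype(bool)
    if y.all() or not y.any():
        raise ValueError("both case and control samples are required")

    Z = zscore_normalize(sub)
    raw = sub.counts
    features = {}
    for j, asv_id in enumerate(feature_ids):
        mean_case = float(Z[y, j].mean())
        mean_control = float(Z[~y, j].mean())
        if mean_case > mean_control:
            direction = "ASD increased"
        elif mean_case < mean_control:
            direction = "ASD decreased"
        else:
            direction = "tied"
        features[asv_id] = FeatureSummary(
            asv_id=asv_id,
            mean_case=mean_case,
            mean_control=mean_control,
            direction=direction,
            absent_in_case=bool((raw[y, j] == 0).all()),
            absent_in_control=bool((raw[~y, j] == 0).all()),
        )
    standardized = pd.DataFrame(Z, index=sub.sample_ids, columns=feature_ids)
    return AbundanceSummary(features=features, standardized=standardized)


def export_heatmap(
    summary: AbundanceSummary | pd.DataFrame,
    tsv_path: str | Path,
    image_path: str | Path | None = None,
) -> None:
    """Write the standardized samples x features matrix as TSV and a heat-map.

    The TSV is the artifact of record (bit-exact, signature column order);
    the rendered image is for inspection only.
    """
    matrix = summary.standardized if isinstance(summary, AbundanceSummary) else summary
    if matrix.empty:
        raise ValueError("nothing to export: empty selection")
    matrix.to_csv(tsv_path, sep="\t", index_label="sample_id")
    if image_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        import seaborn as sns

        height = max(3.0, 0.08 * matrix.shape[0])
        width = max(4.0, 0.3 * matrix.shape[1])
        fig, ax = plt.subplots(figsize=(width, height))
        sns.heatmap(matrix, cmap="vlag", center=0.0, ax=ax, cbar_kws={"label": "Z-score"})
        ax.set_xlabel("ASV (signature rank order)")
        ax.set_ylabel("sample")
        fig.tight_layout()
        fig.savefig(image_path, dpi=150)
        plt.close(fig)
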