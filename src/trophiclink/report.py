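"""Summary classification and report assembly for pipeline runs."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

_ARROWS = {"increasing": "up", "decreasing": "down", "no_change": "flat"}


def classify_overall_trend(slopes: pd.DataFrame, alpha: float = 0.05) -> str:
    """Overall trend direction for one taxon x scale from per-cell slopes.

    The mean cell slope is tested against zero with a one-sample t-test
    across cells; a non-significant mean is reported as ``no_change``.
    """
    vals = np.asarray(slopes["slope"], dtype=float)
    vals = vals[np.isfinite(vals)]
    if len(vals) < 2:
        logger.warning("classify_overall_trend: <2 cells with slopes; reporting no_change")
        return "no_change"
    if np.allclose(vals, vals[0]):
        # degenerate t-test; direction is unambiguous unless all exactly zero
        return "no_change" if vals[0] == 0 else ("increasing" if vals[0] > 0 else "decreasing")
    t, p = stats.ttest_1samp(vals, 0.0)
    if p >= alpha:
        return "no_change"
    return "increasing" if vals.mean() > 0 else "decreasing"


def _md_table(df: pd.DataFrame) -> str:
    header = "| " + " | ".join(df.columns) + " |"
    sep = "|" + "|".join(["---"] * len(df.columns)) + "|"
    body = "\n".join(
        "| " + " | ".join(str(v) for v in row) + " |" for row in df.itertuples(index=False)
    )
    return "\n".join([header, sep, body])


def build_report(
    trends: pd.DataFrame,
    association: pd.DataFrame,
    edm: pd.DataFrame,
    links: pd.DataFrame,
) -> tuple[str, dict]:
    """Assemble report.md text and the mirroring report.json payload.

    Sections: overall trend directions per taxon x scale; association-tier
    agreement/correlation summaries; the EDM winner matrix; and the panel
    link summary (count of significant specifications per insect term).
    """
    parts = ["# Trophic-link pipeline report", ""]
    parts += ["## Overall trend directions", "", _md_table(trends), ""]
    parts += ["## Association tier (trend agreement and remainder correlations)", "",
              _md_table(association), ""]
    if not edm.empty:
        parts += ["## Prediction tier (GP-EDM winner matrix)", "", _md_table(edm), ""]
    parts += ["## Causal-inference tier (link summary)", "", _md_table(links), ""]
    payload = {
        "trends": trends.to_dict(orient="records"),
        "association": association.to_dict(orient="records"),
        "edm": edm.to_dict(orient="records"),
        "links": links.to_dict(orient="records"),
    }
    return "\n".join(parts), payload
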