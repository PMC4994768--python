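"""Summary tables and figures over fitted amplitude estimates.

Group-level statistics here are ordinary one-sample t-tests over
per-recording contrast values — convenience reporting on top of the
per-recording amplitude estimates, which are the method's actual
output.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .glm import GLMResult, contrast

__all__ = ["summarise_betas", "plot_grand_average"]

logger = logging.getLogger(__name__)


def summarise_betas(
    results: list[GLMResult],
    contrast_specs: dict[str, np.ndarray],
) -> pd.DataFrame:
    """Across-recording summary of contrast estimates.

    Parameters
    ----------
    results : list of GLMResult
        One fitted model per recording/subject; all must share the same
        column map.
    contrast_specs : dict
        Maps a contrast name to its per-column weight vector.

    Returns
    -------
    DataFrame with one row per contrast: mean, standard error, n, the
    one-sample t statistic and its two-sided p value.  With a single
    recording the SE, t and p are reported as NaN.
    """
    if not results:
        raise ValueError("no results to summarise")
    cmap = results[0].column_map
    for r in results[1:]:
        if r.column_map != cmap:
            raise ValueError("results have inconsistent column maps")
    rows = []
    for name, weights in contrast_specs.items():
        vals = np.asarray([contrast(r, weights) for r in results])
        n = vals.size
        mean = float(np.mean(vals))
        if n > 1:
            se = float(np.std(vals, ddof=1) / np.sqrt(n))
            tstat = mean / se if se > 0 else np.inf * np.sign(mean)
            p = float(2 * stats.t.sf(abs(tstat), df=n - 1))
        else:
            se = tstat = p = float("nan")
        rows.append(
            {"contrast": name, "mean": mean, "se": se, "n": n, "t": tstat, "p": p}
        )
    return pd.DataFrame(rows, columns=["contrast", "mean", "se", "n", "t", "p"])


def plot_grand_average(
    curves: dict[str, dict[str, np.ndarray]],
    window: tuple[float, float],
    out_dir: str | Path,
    filename: str = "grand_average.png",
) -> Path | None:
    """Plot grand-average peri-event curves, one panel per measure.

    Parameters
    ----------
    curves : {measure: {condition: curve}}
        Mean peri-event curves, all sampled on the same window grid.
    window : (float, float)
        Peri-event window in seconds; the event onset (t = 0) is marked.

    Returns the written file path, or None if there is nothing to plot.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    measures = [m for m, conds in curves.items() if conds]
    if not measures:
        logger.info("no curves to plot; skipping figure")
        return None
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fig, axes = plt.subplots(
        1, len(measures), figsize=(4 * len(measures), 3), squeeze=False
    )
    for ax, measure in zip(axes[0], measures):
        for condition, curve in curves[measure].items():
            t = np.linspace(window[0], window[1], len(curve))
            ax.plot(t, curve, label=condition)
        ax.axvline(0.0, color="k", lw=0.8, ls="--")
        ax.set_title(measure.upper())
        ax.set_xlabel("time from event (s)")
        ax.legend(fontsize="small")
    fig.tight_layout()
    path = out_dir / filename
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
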