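"""Cross-subgroup comparison surfaces: LOD matrices, peak tables, heat maps."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .linkage import LODCurve, lod_to_pvalue

COLUMN_ORDER = ["ALL"] + [
    f"G{k}{suffix}" for k in (1, 2, 3, 4) for suffix in ("", "s", "M", "Fc")
]


class ReportError(ValueError):
    pass


def _check_shared_map(curves: list[LODCurve]) -> LODCurve:
    ref = curves[0]
    for c in curves[1:]:
        if not (
            np.array_equal(c.chromosomes, ref.chromosomes)
            and np.allclose(c.positions_cm, ref.positions_cm)
        ):
            raise ReportError(f"curve {c.label} is on a different map than {ref.label}")
    return ref


def build_matrix(curves: list[LODCurve], cutoff: float = 2.0) -> pd.DataFrame:
    """Positions x subgroups LOD matrix, rows filtered by the display cutoff.

    A row survives iff its maximum across subgroups reaches ``cutoff``;
    rows are ordered genomically, columns in the fixed catalogue order
    (ALL, G1, G1s, G1M, G1Fc, G2, ...), restricted to supplied curves.
    """
    if not curves:
        raise ReportError("no curves supplied")
    ref = _check_shared_map(curves)
    data = {c.label: c.lod for c in curves}
    labels = [l for l in COLUMN_ORDER if l in data]
    labels += [c.label for c in curves if c.label not in labels]
    frame = pd.DataFrame(
        data,
        index=pd.MultiIndex.from_arrays(
            [ref.chromosomes, ref.positions_cm, ref.marker_ids],
            names=["chrom", "pos_cm", "marker_id"],
        ),
    )[labels]
    kept = frame[frame.max(axis=1) >= cutoff]
    if kept.empty:
        warnings.warn(f"no position reaches the LOD cutoff {cutoff}", stacklevel=2)
    return kept


def peak_table(
    curves: list[LODCurve],
    top_k: int = 5,
    min_separation_cm: float = 30.0,
    min_lod_drop: float = 1.0,
) -> pd.DataFrame:
    """Per-cohort ranked linkage peaks.

    Peaks are local maxima of each curve; a candidate close to an accepted
    stronger peak (within ``min_separation_cm`` on the same chromosome) is
    reported only when the curve dips by at least ``min_lod_drop`` between
    them.  Zero-LOD positions never form peaks.
    """
    rows = []
    for curve in curves:
        peaks = _find_peaks(curve, top_k, min_separation_cm, min_lod_drop)
        for i in peaks:
            rows.append(
                {
                    "cohort": curve.label,
                    "chrom": int(curve.chromosomes[i]),
                    "pos_cm": float(curve.positions_cm[i]),
                    "marker_id": curve.marker_ids[i],
                    "lod": float(curve.lod[i]),
                    "p": float(lod_to_pvalue(float(curve.lod[i]))),
                    "n_families": curve.n_families,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["cohort", "chrom", "pos_cm", "marker_id", "lod", "p", "n_families"],
    )


def _find_peaks(
    curve: LODCurve, top_k: int, min_sep: float, min_drop: float
) -> list[int]:
    lod = curve.lod
    candidates = []
    for i in range(len(lod)):
        if lod[i] <= 0:
            continue
        same = curve.chromosomes == curve.chromosomes[i]
        left_ok = i == 0 or not same[i - 1] or lod[i] >= lod[i - 1]
        right_ok = i == len(lod) - 1 or not same[i + 1] or lod[i] > lod[i + 1]
        if left_ok and right_ok:
            candidates.append(i)
    candidates.sort(key=lambda i: -lod[i])
    accepted: list[int] = []
    for i in candidates:
        ok = True
        for j in accepted:
            if curve.chromosomes[i] != curve.chromosomes[j]:
                continue
            if abs(curve.positions_cm[i] - curve.positions_cm[j]) >= min_sep:
                continue
            lo, hi = sorted((i, j))
            sel = slice(lo, hi + 1)
            valley = lod[sel].min()
            if lod[i] - valley < min_drop:
                ok = False
                break
        if ok:
            accepted.append(i)
        if len(accepted) >= top_k:
            break
    return accepted


def plot_heatmap(matrix: pd.DataFrame, path, cutoff: float = 2.0) -> None:
    """Render the LOD matrix as the familiar subgroup x position heat map."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(
        figsize=(max(4, 0.5 * matrix.shape[1]), max(3, 0.25 * matrix.shape[0]))
    )
    im = ax.imshow(matrix.to_numpy(), aspect="auto", cmap="YlOrRd", vmin=cutoff)
    ax.set_xticks(range(matrix.shape[1]), matrix.columns, rotation=90, fontsize=7)
    ax.set_yticks(
        range(matrix.shape[0]),
        [f"chr{c}:{p:.0f}" for c, p, _ in matrix.index],
        fontsize=6,
    )
    fig.colorbar(im, ax=ax, label="LOD")
    ax.set_xlabel("subgroup")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
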