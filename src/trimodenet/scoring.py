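"""Entropy weighting, content adjustment and the final rankings.

The flow matrix ``z`` (m components × n effects) is weighted by the entropy
weight method: each effect column is normalized to proportions
``p_ij = z_ij / Σ_i z_ij``, its Shannon entropy is scaled into [0, 1] by
``k = 1 / ln m``, and low-entropy (more discriminating) effects receive
larger weights

    H_j = -k Σ_i p_ij ln p_ij        ω_j = (1 - H_j) / (n - Σ_j H_j)

with the conventions 0·ln 0 = 0, H_j = 1 for an all-zero column (no
information), and uniform ω when every column is uninformative.  Scores are
then adjusted by each component's content ratio:

    S_ij = z_ij · ω_j · R_i

Effect and component scores are the column and row sums of S; the component
score factors exactly as (network score) × (content ratio), where the
network score is ``Σ_j z_ij ω_j``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import ContentProfile, ValidationError
from .network import FlowScoreMatrix

__all__ = [
    "ScoreTable",
    "entropy_weights",
    "adjust_scores",
    "rank",
    "effect_table",
    "component_table",
    "report_heatmap",
]


def entropy_weights(zm: FlowScoreMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-effect entropies ``H_j`` in [0,1] and weights ``ω_j`` summing to 1."""
    z = zm.z
    m, n = z.shape
    if m < 2:
        raise ValidationError("entropy weights need at least 2 components (k = 1/ln m)")
    k = 1.0 / np.log(m)
    H = np.ones(n)
    for j in range(n):
        total = z[:, j].sum()
        if total <= 0:
            continue  # all-zero column carries no information: H_j = 1
        p = z[:, j] / total
        nz = p[p > 0]
        H[j] = float(-k * np.sum(nz * np.log(nz)))
    H = np.clip(H, 0.0, 1.0)
    denom = n - H.sum()
    if denom <= 0:
        omega = np.full(n, 1.0 / n)
    else:
        omega = (1.0 - H) / denom
    return H, omega


@dataclass(frozen=True)
class ScoreTable:
    """Flow scores with entropy weights, content adjustment and marginals."""

    z: FlowScoreMatrix
    H: np.ndarray
    omega: np.ndarray
    content_ratio: np.ndarray  # aligned with z.components
    adjusted: np.ndarray  # S_ij = z_ij ω_j R_i
    network_score: np.ndarray  # Σ_j z_ij ω_j, per component
    effect_score: np.ndarray  # Σ_i S_ij, per effect
    component_score: np.ndarray  # Σ_j S_ij, per component

    @property
    def components(self) -> tuple[str, ...]:
        return self.z.components

    @property
    def effects(self) -> tuple[str, ...]:
        return self.z.effects

    @property
    def weighted(self) -> np.ndarray:
        """The pre-adjustment matrix ``z_ij ω_j``."""
        return self.z.z * self.omega[None, :]


def adjust_scores(
    zm: FlowScoreMatrix,
    omega: np.ndarray,
    content: ContentProfile,
    H: np.ndarray | None = None,
) -> ScoreTable:
    """Apply entropy weights and content ratios; compute all marginals.

    ``content`` must cover exactly the matrix's components (scores are
    invariant to rescaling all peak areas, only the ratios enter).
    """
    omega = np.asarray(omega, dtype=float)
    if omega.shape != (len(zm.effects),):
        raise ValidationError("omega length does not match the effect axis")
    if not np.isclose(omega.sum(), 1.0):
        raise ValidationError(f"omega must sum to 1, got {omega.sum()}")
    ratios = content.ratios
    missing = set(zm.components) ^ set(ratios)
    if missing:
        raise ValidationError(f"component labels of z and content differ: {sorted(missing)}")
    if H is None:
        H = entropy_weights(zm)[0]

    r = np.array([ratios[c] for c in zm.components])
    weighted = zm.z * omega[None, :]
    adjusted = weighted * r[:, None]
    # marginals via fsum: each is the correctly rounded sum of its row/column,
    # so the effect and component totals are exactly the two marginalizations
    # of the same adjusted matrix
    return ScoreTable(
        z=zm,
        H=np.asarray(H, dtype=float),
        omega=omega,
        content_ratio=r,
        adjusted=adjusted,
        network_score=np.array([math.fsum(row) for row in weighted]),
        effect_score=np.array([math.fsum(col) for col in adjusted.T]),
        component_score=np.array([math.fsum(row) for row in adjusted]),
    )


def _ordered(labels: tuple[str, ...], scores: np.ndarray) -> list[str]:
    return [lab for lab in sorted(labels, key=lambda l: (-scores[labels.index(l)], l))]


def rank(table: ScoreTable) -> tuple[list[str], list[str]]:
    """Effects and components ordered by descending score, ties by label."""
    effects = _ordered(table.effects, table.effect_score)
    components = _ordered(table.components, table.component_score)
    return effects, components


def effect_table(table: ScoreTable) -> pd.DataFrame:
    """Ranked per-effect scores (columns: effect, score)."""
    order, _ = rank(table)
    idx = {e: j for j, e in enumerate(table.effects)}
    return pd.DataFrame(
        {"effect": order, "score": [table.effect_score[idx[e]] for e in order]}
    )


def component_table(table: ScoreTable) -> pd.DataFrame:
    """Ranked per-component scores (component, network_score, content_ratio, score).

    Each row satisfies score = network_score × content_ratio exactly.
    """
    _, order = rank(table)
    idx = {c: i for i, c in enumerate(table.components)}
    return pd.DataFrame(
        {
            "component": order,
            "network_score": [table.network_score[idx[c]] for c in order],
            "content_ratio": [table.content_ratio[idx[c]] for c in order],
            "score": [table.component_score[idx[c]] for c in order],
        }
    )


def report_heatmap(table: ScoreTable, path_prefix: str | Path) -> dict[str, Path]:
    """Write the pre- and post-adjustment score matrices as TSV plus a heatmap.

    Produces ``<prefix>_weighted.tsv`` (z_ij ω_j), ``<prefix>_adjusted.tsv``
    (S_ij) and ``<prefix>_heatmap.png`` with both panels.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    out: dict[str, Path] = {}
    frames = {
        "weighted": pd.DataFrame(
            table.weighted, index=list(table.components), columns=list(table.effects)
        ),
        "adjusted": pd.DataFrame(
            table.adjusted, index=list(table.components), columns=list(table.effects)
        ),
    }
    for key, frame in frames.items():
        out[key] = prefix.with_name(prefix.name + f"_{key}.tsv")
        frame.to_csv(out[key], sep="\t", float_format="%.17g", index_label="component")

    fig, axes = plt.subplots(1, 2, figsize=(4 + len(table.effects), 3 + 0.3 * len(table.components)))
    for ax, (key, frame) in zip(axes, frames.items()):
        im = ax.imshow(frame.values, aspect="auto", cmap="viridis")
        ax.set_xticks(range(len(table.effects)), table.effects, rotation=45, ha="right")
        ax.set_yticks(range(len(table.components)), table.components)
        ax.set_title(key)
        fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    out["png"] = prefix.with_name(prefix.name + "_heatmap.png")
    fig.savefig(out["png"], dpi=120)
    plt.close(fig)
    return out
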