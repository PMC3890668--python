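"""Ordination scatter plots (species-complex assignment figures)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .distances import distance_matrix  # noqa: E402
from .ordination import DelphininaeReport, nmds  # noqa: E402
from .seqio import UNDETERMINED, AlignedSeqSet  # noqa: E402


def plot_assignment(
    reference: AlignedSeqSet,
    queries: AlignedSeqSet | None,
    report: DelphininaeReport,
    seed: int | None,
    k: int,
    restarts: int,
    path: str | Path,
) -> None:
    """Scatter of the joint nMDS embedding, references coloured by species,
    queries in black labelled by their LDA call."""
    merged = reference.concat(queries) if queries is not None else reference
    orde = nmds(distance_matrix(merged), k=k, n_restarts=restarts, seed=seed)
    coords = {lab: xy for lab, xy in zip(orde.labels, orde.coordinates)}
    species = {
        sp.id: sp.species for sp in reference.specimens
        if sp.species != UNDETERMINED
    }
    fig, ax = plt.subplots(figsize=(6, 5))
    for sp_name in sorted(set(species.values())):
        pts = [coords[i] for i, s in species.items() if s == sp_name]
        ax.scatter(*zip(*[(p[0], p[1]) for p in pts]), label=sp_name, s=30)
    if queries is not None:
        calls = report.calls()
        for sp in queries.specimens:
            x, y = coords[sp.id][:2]
            ax.scatter([x], [y], c="black", marker="x", s=40)
            ax.annotate(f"{sp.id} ({calls.get(sp.id, '?')})", (x, y),
                        fontsize=7, xytext=(3, 3), textcoords="offset points")
    ax.set_xlabel("nMDS 1")
    ax.set_ylabel("nMDS 2")
    ax.set_title(f"nMDS of K2P distances (stress-1 = {report.stress:.3f})")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
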