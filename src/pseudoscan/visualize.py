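"""Parameter sweeps over cached searches and simple static plots.

The sweep re-derives pseudogene calls from a cache at every combination
of a truncation-length cutoff and a hit-similarity floor (minimum percent
identity by default), producing the call-count surface users inspect to
pick thresholds. Rendering is deliberately static: a TSV of the grid, a
3D surface image and a per-contig linear call map.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .annotate import AnnotationResult, reannotate
from .config import Thresholds
from .genome_io import GenomeRecord


class VisualizeError(ValueError):
    pass


@dataclass
class SweepGrid:
    length_cutoffs: list
    similarity_cutoffs: list
    counts: list  # rows: length axis; cols: similarity axis

    def __post_init__(self):
        if sorted(self.length_cutoffs) != list(self.length_cutoffs):
            raise VisualizeError("length cutoffs must be ascending")
        if sorted(self.similarity_cutoffs) != list(self.similarity_cutoffs):
            raise VisualizeError("similarity cutoffs must be ascending")
        if len(self.counts) != len(self.length_cutoffs) or any(
            len(row) != len(self.similarity_cutoffs) for row in self.counts
        ):
            raise VisualizeError("count matrix does not match axes")
        if any(c < 0 for row in self.counts for c in row):
            raise VisualizeError("negative count")


def parameter_sweep(cache_path: str, genome: GenomeRecord,
                    length_cutoffs: list, similarity_cutoffs: list,
                    base: Thresholds | None = None) -> SweepGrid:
    """Call counts from the cache at every cutoff combination.

    ``counts[i][j]`` is the number of consolidated pseudogene calls under
    ``length_ratio_min = length_cutoffs[i]`` and a hit percent-identity
    floor of ``similarity_cutoffs[j]``; every cell is computed by the same
    re-derivation as ``reannotate``.
    """
    if not length_cutoffs or not similarity_cutoffs:
        raise VisualizeError("each sweep axis needs at least one value")
    base = base or Thresholds()
    counts = []
    for lc in length_cutoffs:
        row = []
        for sc in similarity_cutoffs:
            t = base.replace(length_ratio_min=lc, min_identity=sc)
            result = reannotate(cache_path, genome, t)
            row.append(len(result.calls))
        counts.append(row)
    return SweepGrid(list(length_cutoffs), list(similarity_cutoffs), counts)


def write_grid_tsv(grid: SweepGrid, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(
            "length_cutoff\t"
            + "\t".join(format(s, "g") for s in grid.similarity_cutoffs)
            + "\n"
        )
        for lc, row in zip(grid.length_cutoffs, grid.counts):
            fh.write(format(lc, "g") + "\t" + "\t".join(str(c) for c in row) + "\n")


def read_grid_tsv(path: str) -> SweepGrid:
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        similarity = [float(x) for x in header[1:]]
        lengths, counts = [], []
        for line in fh:
            cols = line.rstrip("\n").split("\t")
            lengths.append(float(cols[0]))
            counts.append([int(x) for x in cols[1:]])
    return SweepGrid(lengths, similarity, counts)


REASON_COLORS = {
    "short": "#d62728",
    "run_on": "#9467bd",
    "fragmented": "#ff7f0e",
    "intergenic_remnant": "#8c564b",
    "high_dnds": "#e377c2",
    "frameshift": "#2ca02c",
    "nonsense": "#1f77b4",
    "start_lost": "#bcbd22",
    "stop_lost": "#17becf",
}


def render(grid: SweepGrid, result: AnnotationResult, genome: GenomeRecord,
           outdir: str) -> dict:
    """Write the sweep TSV, the 3D count surface and a linear call map."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "tsv": os.path.join(outdir, "sweep.tsv"),
        "surface": os.path.join(outdir, "sweep_surface.png"),
        "map": os.path.join(outdir, "genome_map.png"),
    }
    write_grid_tsv(grid, paths["tsv"])

    fig = plt.figure(figsize=(7, 5))
    ax = fig.add_subplot(111, projection="3d")
    X, Y = np.meshgrid(grid.similarity_cutoffs, grid.length_cutoffs)
    Z = np.array(grid.counts, dtype=float)
    if Z.size > 1 and (len(grid.length_cutoffs) > 1 and len(grid.similarity_cutoffs) > 1):
        ax.plot_surface(X, Y, Z, cmap="viridis", edgecolor="k", linewidth=0.3)
    else:
        ax.scatter(X.ravel(), Y.ravel(), Z.ravel(), c="tab:blue")
    ax.set_xlabel("similarity floor (% identity)")
    ax.set_ylabel("length-ratio cutoff")
    ax.set_zlabel("pseudogene calls")
    fig.tight_layout()
    fig.savefig(paths["surface"], dpi=110)
    plt.close(fig)

    called = result.called_loci()
    contigs = list(genome.contigs)
    fig, axes = plt.subplots(
        len(contigs), 1, figsize=(10, 1.6 * len(contigs)), squeeze=False
    )
    for ax, cid in zip(axes[:, 0], contigs):
        ax.set_xlim(0, len(genome.contigs[cid]))
        ax.set_ylim(0, 2)
        ax.set_yticks([])
        ax.set_title(cid, fontsize=8, loc="left")
        for f in genome.cds_features():
            if f.interval.contig_id != cid or f.locus_tag in called:
                continue
            ax.broken_barh(
                [(f.interval.start, len(f.interval))], (1.1, 0.6), color="#bbbbbb"
            )
        for call in result.calls:
            if call.interval.contig_id != cid:
                continue
            reason = sorted(call.reasons)[0]
            ax.broken_barh(
                [(call.interval.start, len(call.interval))],
                (0.3, 0.6),
                color=REASON_COLORS.get(reason, "#000000"),
            )
    fig.tight_layout()
    fig.savefig(paths["map"], dpi=110)
    plt.close(fig)
    return paths
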