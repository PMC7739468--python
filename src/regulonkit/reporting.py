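"""Gene-centered outputs: CSV reports, the regulon heatmap matrix, figures.

The central artifact is the regulon matrix: one row per ortholog group, one
column per species, cells holding the posterior probability of regulation of
the gene's operon in that species (empty where the species lacks an ortholog
— absence is a category of its own, not zero probability).  Rows are sorted
by descending average posterior over present members.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd

from .ancestral_recon import AncestralReport
from .errors import InputError
from .motif_model import PSWM, format_jaspar_counts
from .orthologs import OrthologGroup


@dataclass(frozen=True)
class RegulonMatrix:
    """Ortholog-group x species matrix of regulation posteriors."""

    table: pd.DataFrame  # index: group_id; columns: species; NaN = absent
    averages: pd.Series  # per-group average posterior over present members


def build_regulon_matrix(groups: list[OrthologGroup], species_order: list[str]) -> RegulonMatrix:
    """Assemble and sort the matrix: descending average posterior, ties by
    lexicographic group id; averages run over present members only."""
    rows, averages = {}, {}
    for g in groups:
        rows[g.group_id] = {
            s: g.posteriors.get(s, np.nan) if s in g.members else np.nan
            for s in species_order
        }
        averages[g.group_id] = g.average_posterior
    table = pd.DataFrame.from_dict(rows, orient="index").reindex(columns=species_order)
    avg = pd.Series(averages, dtype=float)
    order = sorted(avg.index, key=lambda gid: (-avg[gid], gid))
    return RegulonMatrix(table=table.loc[order], averages=avg.loc[order])


def read_regulon_matrix(path: Path) -> RegulonMatrix:
    df = pd.read_csv(path, index_col=0)
    avg = df.pop("average_posterior")
    return RegulonMatrix(table=df, averages=avg)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(path: Path, header: list[str], rows: list[list]) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)  # RFC-4180 quoting
        writer.writerow(header)
        writer.writerows(rows)


SITES_HEADER = ["species", "operon_id", "locus_tag", "position", "strand",
                "site_sequence", "score_bits", "p_regulated"]
OPERONS_HEADER = ["species", "operon_id", "strand", "locus_tags",
                  "promoter_contig", "promoter_start", "promoter_end", "p_regulated"]
GROUPS_HEADER_PREFIX = ["group_id"]
ANCESTRAL_HEADER = ["group_id", "node_id", "P(s0)", "P(s1)", "P(sa)"]


def write_reports(
    matrix: RegulonMatrix,
    sites: list[list],
    operons: list[list],
    mixtures: dict[str, PSWM],
    ancestral: list[AncestralReport],
    out_dir: Path,
    tree_newick: str = "",
    figures: bool = False,
) -> dict[str, str]:
    """Write all CSV products (plus optional figures); returns the manifest
    mapping file name -> sha256 of content.  Deterministic for fixed inputs."""
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise InputError(f"cannot create output directory {out_dir}: {exc}")

    written: list[Path] = []

    path = out_dir / "sites.csv"
    _write_csv(path, SITES_HEADER, sites)
    written.append(path)

    path = out_dir / "operons.csv"
    _write_csv(path, OPERONS_HEADER, operons)
    written.append(path)

    species = list(matrix.table.columns)
    path = out_dir / "ortholog_groups.csv"
    rows = []
    for gid in matrix.table.index:
        cells = ["" if pd.isna(matrix.table.loc[gid, s]) else f"{matrix.table.loc[gid, s]:.6f}"
                 for s in species]
        rows.append([gid] + cells + [f"{matrix.averages[gid]:.6f}"])
    _write_csv(path, GROUPS_HEADER_PREFIX + species + ["average_posterior"], rows)
    written.append(path)

    path = out_dir / "ancestral_states.csv"
    arows = []
    for rep in ancestral:
        for node in sorted(rep.node_probabilities):
            p = rep.node_probabilities[node]
            arows.append([rep.group_id, node] + [f"{x:.6f}" for x in p])
    _write_csv(path, ANCESTRAL_HEADER, arows)
    written.append(path)

    path = out_dir / "mixture_pswms.txt"
    path.write_text("".join(format_jaspar_counts(sid, p) for sid, p in sorted(mixtures.items())),
                    encoding="utf-8")
    written.append(path)

    if tree_newick:
        path = out_dir / "tf_tree.nwk"
        path.write_text(tree_newick + "\n", encoding="utf-8")
        written.append(path)

    empty = matrix.table.empty
    if figures and not empty:
        written.append(_heatmap_figure(matrix, out_dir / "regulon_heatmap.png"))

    manifest = {p.name: _sha256(p) for p in written}
    manifest_payload = {"files": manifest, "empty_regulon": bool(empty)}
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest_payload, indent=2, sort_keys=True), encoding="utf-8"
    )
    return manifest


def _heatmap_figure(matrix: RegulonMatrix, path: Path) -> Path:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import LinearSegmentedColormap

    # green = regulated, red = not; absent cells masked blue
    cmap = LinearSegmentedColormap.from_list("reg", ["red", "yellow", "green"])
    cmap.set_bad("blue")
    data = np.ma.masked_invalid(matrix.table.to_numpy(dtype=float))
    fig, ax = plt.subplots(figsize=(2 + 0.5 * matrix.table.shape[1],
                                    1 + 0.25 * matrix.table.shape[0]))
    ax.imshow(data, aspect="auto", cmap=cmap, vmin=0, vmax=1)
    ax.set_xticks(range(matrix.table.shape[1]), matrix.table.columns, rotation=90)
    ax.set_yticks(range(matrix.table.shape[0]), matrix.table.index, fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
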