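"""Dataset readers/writers, checkpoints, and prediction evaluation.

On disk a dataset is a directory with one sub-directory per section:

    <root>/<section_id>/spots.csv        spot_id,row,col[,pixel_x,pixel_y]
    <root>/<section_id>/counts.csv       spots x genes, spot ids as index
                         (or counts.mtx + genes.txt + spots.txt)
    <root>/<section_id>/features.csv     spots x D_X, spot ids as index
    <root>/<section_id>/annotation.csv   spot_id,region_label   (optional)
    <root>/<section_id>/nuclei.csv       spots x nuclei types   (optional)

All per-section matrices are validated against the canonical row-major
spot order of the spot table.  Checkpoints are JSON (deterministic bytes
for a given model).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp

from .data import CountMatrix, ExpressionMatrix, FeatureMatrix, Section
from .graph import SpotGrid, build_grid_graph
from .preprocessing import normalize_counts

__all__ = [
    "write_section",
    "load_section",
    "load_dataset",
    "write_dataset",
    "evaluate_predictions",
    "save_checkpoint",
    "load_checkpoint",
]


def write_section(section: Section, out_dir: str | Path, sparse_counts=False):
    """Write one section's tables under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    grid = section.grid
    spot_tbl = pd.DataFrame(
        {
            "spot_id": list(grid.spot_ids),
            "row": grid.grid_coords[:, 0],
            "col": grid.grid_coords[:, 1],
        }
    )
    if grid.pixel_coords is not None:
        spot_tbl["pixel_x"] = grid.pixel_coords[:, 0]
        spot_tbl["pixel_y"] = grid.pixel_coords[:, 1]
    spot_tbl.to_csv(out / "spots.csv", index=False)

    if section.counts is not None:
        if sparse_counts:
            sio.mmwrite(
                str(out / "counts.mtx"), sp.coo_matrix(section.counts.values)
            )
            (out / "genes.txt").write_text(
                "\n".join(map(str, section.counts.gene_ids)) + "\n"
            )
            (out / "spots.txt").write_text(
                "\n".join(map(str, grid.spot_ids)) + "\n"
            )
        else:
            pd.DataFrame(
                section.counts.values,
                index=list(grid.spot_ids),
                columns=list(section.counts.gene_ids),
            ).to_csv(out / "counts.csv")

    pd.DataFrame(
        section.features.values,
        index=list(grid.spot_ids),
        columns=[f"f{j}" for j in range(section.features.dim)],
    ).to_csv(out / "features.csv")

    if section.annotation is not None:
        keep = [a is not None for a in section.annotation]
        pd.DataFrame(
            {
                "spot_id": np.asarray(grid.spot_ids, object)[keep],
                "region_label": section.annotation[keep],
            }
        ).to_csv(out / "annotation.csv", index=False)

    if section.nuclei_proportions is not None:
        cols = section.nuclei_types or [
            f"nuclei_{t}" for t in range(section.nuclei_proportions.shape[1])
        ]
        pd.DataFrame(
            section.nuclei_proportions,
            index=list(grid.spot_ids),
            columns=list(cols),
        ).to_csv(out / "nuclei.csv")


def _check_ids(name: str, found, expected):
    found = list(map(str, found))
    expected = list(map(str, expected))
    if found != expected:
        unknown = sorted(set(found) - set(expected))
        missing = sorted(set(expected) - set(found))
        raise ValueError(
            f"{name}: spot ids do not match the spot table"
            + (f"; unknown ids {unknown[:5]}" if unknown else "")
            + (f"; missing ids {missing[:5]}" if missing else "")
        )


def load_section(sec_dir: str | Path, feature_kind="synthetic") -> Section:
    """Load one section directory, validating id consistency."""
    sec = Path(sec_dir)
    spot_tbl = pd.read_csv(sec / "spots.csv")
    px = None
    if {"pixel_x", "pixel_y"} <= set(spot_tbl.columns):
        px = spot_tbl[["pixel_x", "pixel_y"]].to_numpy(float)
    grid = SpotGrid.from_unsorted(
        spot_tbl["spot_id"].astype(str).tolist(),
        spot_tbl[["row", "col"]].to_numpy(int),
        px,
    )

    counts = None
    if (sec / "counts.csv").exists():
        tbl = pd.read_csv(sec / "counts.csv", index_col=0)
        _check_ids("counts.csv", tbl.index, grid.spot_ids)
        counts = CountMatrix(
            tbl.to_numpy(), tuple(tbl.columns), sec.name
        )
    elif (sec / "counts.mtx").exists():
        mat = sio.mmread(str(sec / "counts.mtx")).toarray()
        genes = (sec / "genes.txt").read_text().split()
        spots = (sec / "spots.txt").read_text().split()
        _check_ids("counts.mtx", spots, grid.spot_ids)
        counts = CountMatrix(mat, tuple(genes), sec.name)

    feat_tbl = pd.read_csv(sec / "features.csv", index_col=0)
    _check_ids("features.csv", feat_tbl.index, grid.spot_ids)
    features = FeatureMatrix(feat_tbl.to_numpy(float), feature_kind)

    annotation = None
    if (sec / "annotation.csv").exists():
        ann_tbl = pd.read_csv(sec / "annotation.csv")
        lookup = dict(
            zip(ann_tbl["spot_id"].astype(str), ann_tbl["region_label"])
        )
        unknown = set(lookup) - set(map(str, grid.spot_ids))
        if unknown:
            raise ValueError(
                f"annotation.csv: unknown spot ids {sorted(unknown)[:5]}"
            )
        annotation = np.array(
            [lookup.get(str(s)) for s in grid.spot_ids], dtype=object
        )

    nuclei, nuclei_types = None, None
    if (sec / "nuclei.csv").exists():
        nuc_tbl = pd.read_csv(sec / "nuclei.csv", index_col=0)
        _check_ids("nuclei.csv", nuc_tbl.index, grid.spot_ids)
        nuclei = nuc_tbl.to_numpy(float)
        nuclei_types = tuple(nuc_tbl.columns)

    return Section(
        section_id=sec.name,
        grid=grid,
        graph=build_grid_graph(grid),
        features=features,
        expression=normalize_counts(counts) if counts is not None else None,
        counts=counts,
        annotation=annotation,
        nuclei_proportions=nuclei,
        nuclei_types=nuclei_types,
    )


def write_dataset(sections, root: str | Path, sparse_counts=False):
    root = Path(root)
    for sec in sections:
        write_section(sec, root / sec.section_id, sparse_counts)


def load_dataset(root: str | Path, feature_kind="synthetic") -> list[Section]:
    """Load every section directory under ``root`` (sorted by name)."""
    root = Path(root)
    sec_dirs = sorted(
        d for d in root.iterdir() if d.is_dir() and (d / "spots.csv").exists()
    )
    if not sec_dirs:
        raise ValueError(f"no section directories under {root}")
    sections = [load_section(d, feature_kind) for d in sec_dirs]
    gene_axes = {
        s.counts.gene_ids for s in sections if s.counts is not None
    }
    if len(gene_axes) > 1:
        raise ValueError("sections disagree on the gene axis")
    return sections


def evaluate_predictions(pred: np.ndarray, target) -> dict:
    """Per-element MSE and mean per-gene Pearson correlation.

    Constant gene columns (in prediction or target) have undefined
    correlation; they are excluded from the mean and counted.
    Returns a dict with ``mse``, ``pcc`` (mean over valid genes),
    ``n_constant_genes`` and a per-gene table.
    """
    y = np.asarray(getattr(target, "values", target), float)
    p = np.asarray(pred, float)
    if p.shape != y.shape:
        raise ValueError("prediction and target shapes differ")
    mse = float(((p - y) ** 2).mean())
    pc = p - p.mean(axis=0)
    tc = y - y.mean(axis=0)
    pn = np.sqrt((pc**2).sum(axis=0))
    tn = np.sqrt((tc**2).sum(axis=0))
    ok = (pn > 1e-12) & (tn > 1e-12)
    r = np.full(p.shape[1], np.nan)
    r[ok] = (pc[:, ok] * tc[:, ok]).sum(axis=0) / (pn[ok] * tn[ok])
    gene_ids = getattr(target, "gene_ids", None) or tuple(range(p.shape[1]))
    per_gene = pd.DataFrame(
        {
            "gene": list(gene_ids),
            "mse": ((p - y) ** 2).mean(axis=0),
            "pcc": r,
        }
    ).sort_values("pcc", ascending=False, kind="stable")
    return {
        "mse": mse,
        "pcc": float(np.nanmean(r)) if ok.any() else float("nan"),
        "n_constant_genes": int((~ok).sum()),
        "per_gene": per_gene,
    }


def save_checkpoint(path: str | Path, model, extra: dict | None = None):
    """Serialize a fitted regressor (and optional W0) to deterministic JSON."""
    payload = {
        "weights": [w.tolist() for w in model.regressor_.weights_]
        if hasattr(model, "regressor_")
        else [w.tolist() for w in model.weights_],
        "self_loops": getattr(model, "self_loops", True),
        "params": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in model.get_params().items()
        },
    }
    if hasattr(model, "projection_"):
        payload["w0"] = model.projection_.w0.tolist()
    if extra:
        payload["extra"] = extra
    Path(path).write_text(
        json.dumps(payload, sort_keys=True, separators=(",", ":"))
    )


def load_checkpoint(path: str | Path) -> dict:
    payload = json.loads(Path(path).read_text())
    payload["weights"] = [np.array(w) for w in payload["weights"]]
    if "w0" in payload:
        payload["w0"] = np.array(payload["w0"])
    return payload
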