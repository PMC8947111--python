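"""Batch processing over image-set manifests.

A manifest is a CSV with one row per image set and columns ``set_id``,
``laminin``, ``dapi``, ``marker``, ``sirius`` (each path optional) and
``um_per_px``.  Each set runs whichever pipelines its channels allow; one
failed set is recorded and the batch continues.  Aggregate statistics are
recomputed from the per-object tables so the summary CSV is always
consistent with them.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .config import default_config, ecm_config, fiber_config, macrophage_config, nuclei_config
from .ecm import quantify_ecm
from .fibers import segment_fibers
from .io import read_image
from .macrophages import detect_macrophages
from .nuclei import classify_cnf, segment_nuclei
from .overlay import save_overlay

log = logging.getLogger(__name__)

MANIFEST_COLUMNS = ("set_id", "laminin", "dapi", "marker", "sirius", "um_per_px")

SUMMARY_COLUMNS = [
    "set_id",
    "status",
    "error",
    "n_fibers",
    "mean_mfd",
    "median_mfd",
    "mean_csa",
    "n_nuclei",
    "pct_cnf",
    "pct_pnf",
    "mean_nuclei_per_cnf",
    "n_macrophage_objects",
    "pct_macrophages",
    "ecm_positive_px",
    "ecm_positive_um2",
    "ecm_positive_fraction",
]


def read_manifest(path) -> pd.DataFrame:
    mf = pd.read_csv(path)
    if "set_id" not in mf.columns:
        raise ValueError("manifest requires a set_id column")
    for col in MANIFEST_COLUMNS:
        if col not in mf.columns:
            mf[col] = np.nan
    return mf


def _has(row, col) -> bool:
    return isinstance(row[col], str) and row[col].strip() != ""


def process_set(row, cfg: dict, out_dir: Path) -> dict:
    """Run the configured pipelines for one manifest row."""
    out_dir.mkdir(parents=True, exist_ok=True)
    um = None if pd.isna(row.get("um_per_px")) else float(row["um_per_px"])
    result: dict = {"set_id": row["set_id"], "status": "ok", "error": ""}

    fibers = None
    if _has(row, "laminin"):
        laminin = read_image(row["laminin"], um)
        fibers = segment_fibers(laminin, fiber_config(cfg, um))
        fibers.records.to_csv(out_dir / "fibers.csv", index=False)
        mfd = fibers.records["mfd_um"] if "mfd_um" in fibers.records else fibers.records["mfd_px"]
        csa = fibers.records["csa_um2"] if "csa_um2" in fibers.records else fibers.records["area_px"]
        result.update(
            n_fibers=int(len(fibers.records)),
            mean_mfd=float(mfd.mean()) if len(mfd) else np.nan,
            median_mfd=float(mfd.median()) if len(mfd) else np.nan,
            mean_csa=float(csa.mean()) if len(csa) else np.nan,
        )
        save_overlay(
            out_dir / "fibers_overlay.png",
            laminin.pixels,
            [(fibers.discarded, "yellow"), (fibers.kept, "red")],
        )

    nuclei = None
    if _has(row, "dapi"):
        dapi = read_image(row["dapi"], um)
        nuclei = segment_nuclei(dapi, nuclei_config(cfg))
        result.update(n_nuclei=int(nuclei.max()))
        if fibers is not None:
            per_fiber, summary = classify_cnf(fibers.kept, nuclei, nuclei_config(cfg))
            merged = fibers.records.drop(columns=["cnf_class", "n_nuclei"]).merge(
                per_fiber, on="label", how="left"
            )
            merged.to_csv(out_dir / "fibers.csv", index=False)
            result.update(
                pct_cnf=summary["pct_cnf"],
                pct_pnf=summary["pct_pnf"],
                mean_nuclei_per_cnf=summary["mean_nuclei_per_cnf"],
            )

    if _has(row, "marker") and nuclei is not None:
        marker = read_image(row["marker"], um)
        macro = detect_macrophages(marker, nuclei, macrophage_config(cfg))
        result.update(
            n_macrophage_objects=macro.summary["n_macrophage_objects"],
            pct_macrophages=macro.summary["pct_macrophages"],
        )

    if _has(row, "sirius"):
        sirius = read_image(row["sirius"], um)
        ecm = quantify_ecm(sirius, ecm_config(cfg))
        pd.DataFrame(
            [
                {
                    "positive_px": ecm.positive_px,
                    "positive_um2": ecm.positive_um2,
                    "section_px": ecm.section_px,
                    "positive_fraction": ecm.positive_fraction,
                    "positive_fraction_whole_image": ecm.positive_fraction_whole_image,
                }
            ]
        ).to_csv(out_dir / "ecm.csv", index=False)
        result.update(
            ecm_positive_px=ecm.positive_px,
            ecm_positive_um2=ecm.positive_um2,
            ecm_positive_fraction=ecm.positive_fraction,
        )
    return result


def run_batch(manifest, config: dict | None = None, out_dir=".") -> pd.DataFrame:
    """Process every manifest row; returns (and writes) the aggregate table.

    Unreadable files mark the row as failed without stopping the batch.
    """
    cfg = config or default_config()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    mf = manifest if isinstance(manifest, pd.DataFrame) else read_manifest(manifest)
    rows = []
    for _, row in mf.iterrows():
        set_dir = out_dir / str(row["set_id"])
        try:
            rows.append(process_set(row, cfg, set_dir))
        except (OSError, ValueError) as exc:
            log.warning("set %s failed: %s", row["set_id"], exc)
            rows.append({"set_id": row["set_id"], "status": "failed", "error": str(exc)})
    summary = pd.DataFrame(rows).reindex(columns=SUMMARY_COLUMNS)
    summary.to_csv(out_dir / "aggregate.csv", index=False)
    n_failed = int((summary["status"] == "failed").sum())
    log.info("batch complete: %d sets, %d failed", len(summary), n_failed)
    return summary
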