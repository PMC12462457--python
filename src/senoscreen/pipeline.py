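"""End-to-end orchestration: simulate -> count -> screen -> signature.

Each run writes its tables plus a machine-readable provenance manifest
(inputs, seeds, thresholds, package version, per-stage timing) so results
can be reproduced byte-for-byte from the config alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io, rnaseq, screen as screen_stats, signature as sig
from . import synthetic
from .imaging import SegmentationConfig, aggregate_well, segment_and_count_field

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


@dataclass
class ScreenConfig:
    n_compounds: int = 200
    n_senolytics: int = 5
    senolytic_kill: float = 0.95
    background_kill: float = 0.0
    concentrations: tuple[float, ...] = (1.0, 5.0)
    conditions: tuple[str, ...] = ("CP", "CX")
    n_replicates: int = 2
    well_noise_cv: float = 0.15
    baseline_count: float = 5000.0
    plate_effect_range: tuple[float, float] = (0.5, 2.0)
    z_threshold: float = -3.0


@dataclass
class SignatureConfig:
    n_genes: int = 2000
    n_celllines: int = 5
    n_replicates: int = 5
    n_up: int = 13
    n_down: int = 22
    lfc_up: float = 4.0
    lfc_down: float = -4.0
    dispersion: float = 0.05
    alpha: float = 0.01
    mad_k: float = 2.0
    fc_threshold: float = 1.5
    n_perm: int = 1000


@dataclass
class RunConfig:
    """Full pipeline configuration; round-trips losslessly through YAML."""

    seed: int = 0
    out_dir: str = "senoscreen_out"
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    signature: SignatureConfig = field(default_factory=SignatureConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        def build(klass, data):
            fields = {f.name: f for f in dataclasses.fields(klass)}
            kwargs = {}
            for key, val in (data or {}).items():
                if key not in fields:
                    raise ValueError(f"unknown config key {key!r} for {klass.__name__}")
                if isinstance(val, list):
                    val = tuple(val)
                kwargs[key] = val
            return klass(**kwargs)

        cfg = cls(
            seed=raw.get("seed", 0),
            out_dir=raw.get("out_dir", "senoscreen_out"),
            screen=build(ScreenConfig, raw.get("screen")),
            signature=build(SignatureConfig, raw.get("signature")),
            segmentation=build(SegmentationConfig, raw.get("segmentation")),
        )
        return cfg


class _Manifest:
    def __init__(self, config: RunConfig, stage: str):
        self.data = {
            "tool": "senoscreen",
            "version": __version__,
            "stage": stage,
            "seed": config.seed,
            "config": dataclasses.asdict(config),
            "stages": [],
            "outputs": [],
        }
        self._t0 = None
        self._name = None

    def start(self, name: str) -> None:
        self._name, self._t0 = name, time.perf_counter()

    def done(self) -> None:
        self.data["stages"].append(
            {"name": self._name, "seconds": round(time.perf_counter() - self._t0, 3)}
        )

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.data, fh, indent=2, default=str)


def _stage(manifest: _Manifest, name: str):
    class _Ctx:
        def __enter__(self):
            manifest.start(name)

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise StageError(f"stage {name!r} failed: {exc}") from exc
            manifest.done()

    return _Ctx()


def run_screen_pipeline(config: RunConfig) -> dict:
    """Synthetic counts -> fold changes -> robust Z -> hit list.

    Writes platemap.csv, counts.csv, screen_results.tsv, hits.txt and
    manifest.json under ``config.out_dir``; returns the result paths plus
    the hit set and planted truth for programmatic use.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sc = config.screen
    manifest = _Manifest(config, "screen")

    with _stage(manifest, "simulate"):
        compounds = [f"CMP{i + 1:04d}" for i in range(sc.n_compounds)]
        senolytics = compounds[: sc.n_senolytics]
        platemap = synthetic.design_screen_layout(
            compounds, sc.concentrations, sc.conditions, sc.n_replicates
        )
        truth = synthetic.make_screen_truth(
            platemap,
            senolytic_ids=senolytics,
            senolytic_kill=sc.senolytic_kill,
            background_kill=sc.background_kill,
            plate_effect_range=sc.plate_effect_range,
            well_noise_cv=sc.well_noise_cv,
            baseline_count=sc.baseline_count,
            seed=config.seed,
        )
        counts = synthetic.gen_screen_plates(platemap, truth)
        io.write_platemap(platemap, out / "platemap.csv")
        io.write_counts(counts, out / "counts.csv")

    with _stage(manifest, "score"):
        scored, hits = screen_stats.analyze_screen(
            counts, platemap, z_threshold=sc.z_threshold,
            required_conditions=sc.conditions,
        )
        scored.to_csv(out / "screen_results.tsv", sep="\t", index=False)
        (out / "hits.txt").write_text("\n".join(sorted(hits)) + ("\n" if hits else ""))

    manifest.data["outputs"] = ["platemap.csv", "counts.csv",
                                "screen_results.tsv", "hits.txt"]
    manifest.write(out / "manifest.json")
    return {
        "scored": scored, "hits": hits, "planted": set(senolytics),
        "platemap": platemap, "counts": counts, "truth": truth, "out_dir": out,
    }


def run_signature_pipeline(config: RunConfig) -> dict:
    """Synthetic counts -> DE per contrast -> signature -> scores -> enrichment."""
    from .enrichment import preranked_enrichment

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gc = config.signature
    manifest = _Manifest(config, "signature")

    with _stage(manifest, "simulate"):
        up = tuple(f"UP{i + 1:03d}" for i in range(gc.n_up))
        down = tuple(f"DN{i + 1:03d}" for i in range(gc.n_down))
        truth = synthetic.ExpressionTruth(
            planted_up=up, planted_down=down, n_genes=gc.n_genes,
            n_celllines=gc.n_celllines, n_replicates=gc.n_replicates,
            lfc_up=gc.lfc_up, lfc_down=gc.lfc_down,
            dispersion=gc.dispersion, seed=config.seed,
        )
        counts, samples = synthetic.gen_expression(truth)
        io.write_expression(counts, samples, out / "expression.tsv",
                            out / "samples.csv")

    with _stage(manifest, "differential-expression"):
        tables = []
        logcpm_all = rnaseq.log_cpm(counts, method="tmm-cpm")
        for (line, drug), grp in samples.groupby(["cell_line", "drug"]):
            cols = grp.sample_id.tolist()
            det = sig.DETable(
                rnaseq.simple_de(logcpm_all[cols], grp.group.to_numpy()),
                cell_line=line, drug=drug,
            )
            io.write_de_table(det, out / f"de_{line}_{drug}.tsv")
            tables.append(det)

    with _stage(manifest, "derive"):
        signature = sig.derive_signature(tables, alpha=gc.alpha, name="TIS")
        io.write_gmt(signature, out / "signature.gmt")
        io.write_signature_tsv(signature, out / "signature.tsv")

    with _stage(manifest, "score"):
        if signature.up or signature.down:
            scores = sig.score_signature(logcpm_all, signature)
            labels = sig.classify_high(scores, k=gc.mad_k)
            pd.DataFrame({"sample": scores.index, "score": scores.to_numpy(),
                          "class": labels.to_numpy()}).to_csv(
                out / "scores.tsv", sep="\t", index=False)
        else:
            scores = labels = None
            logger.warning("empty signature: scoring skipped")

    with _stage(manifest, "enrich"):
        enrichment = None
        if signature.up:
            ranked = tables[0].table.set_index("gene_id").log2_fc
            enrichment = preranked_enrichment(
                ranked, signature.up, n_perm=gc.n_perm, seed=config.seed
            )
            with open(out / "enrichment.json", "w") as fh:
                json.dump(dataclasses.asdict(enrichment), fh, indent=2)

    manifest.write(out / "manifest.json")
    return {
        "signature": signature, "truth": truth, "tables": tables,
        "scores": scores, "labels": labels, "samples": samples,
        "enrichment": enrichment, "out_dir": out,
    }


def count_image_directory(
    directory: str | Path, cfg: SegmentationConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Segment every complete TIFF field pair in a directory.

    Returns (per-field counts, per-well aggregated counts).
    """
    field_rows = []
    for plate, well, fld in io.iter_field_keys(directory):
        result = segment_and_count_field(io.read_field(directory, plate, well, fld), cfg)
        field_rows.append((plate, well, fld, result.live_count,
                           result.dead_excluded_count))
    fields = pd.DataFrame(
        field_rows, columns=["plate", "well", "field", "live_count", "dead_excluded"]
    )
    wells = (
        fields.groupby(["plate", "well"], as_index=False)
        .live_count.sum()
        .rename(columns={"plate": "plate_id", "well": "well_id",
                         "live_count": "count"})
    )
    return fields, wells


def make_fixtures(config: RunConfig, n_fields: int = 3, cells_per_field: int = 20) -> dict:
    """Write a small self-consistent dataset for tests and demos.

    Produces a handful of TIFF fields with truth, a compact screen
    (plates, counts, hits) and an expression study (matrix, DE tables,
    signature) under ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    img_dir = out / "images"
    truth_rows = []
    for i in range(n_fields):
        truth = synthetic.random_field_truth(
            n_live=cells_per_field, n_dead=max(1, cells_per_field // 5),
            seed=int(rng.integers(2**31)),
        )
        fld = synthetic.gen_field(truth)
        fld.plate, fld.well, fld.field = "FIX1", "A01", i + 1
        io.write_field(fld, img_dir)
        truth_rows.append(("FIX1", "A01", i + 1, truth.live_count, truth.dead_count))
    pd.DataFrame(
        truth_rows, columns=["plate", "well", "field", "live_truth", "dead_truth"]
    ).to_csv(out / "field_truth.csv", index=False)

    screen_out = run_screen_pipeline(
        dataclasses.replace(config, out_dir=str(out / "screen"))
    )
    signature_out = run_signature_pipeline(
        dataclasses.replace(config, out_dir=str(out / "signature"))
    )
    return {"images": img_dir, "screen": screen_out, "signature": signature_out}
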