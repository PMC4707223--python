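"""End-to-end orchestration: config, staged computation, report bundle."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import call_identity, rank_variants
from .decomposition import contribution_percent, group_coordination
from .errors import DegenerateDeviationError, EmptySelectionError, PepcoordError
from .paircorr import (
    build_histogram,
    coordination_delta,
    cumulative_profile,
    pdf_from_histogram,
    rdf_from_pdf,
)
from .protonation import ProtonationScheme, protonate
from .sro_stats import cluster_stats
from .structure_io import StructureModel, bulk_properties, extract_environment, read_pdb

log = logging.getLogger("pepcoord")

_FLOAT_FMT = "%.10g"


@dataclass
class StructureInput:
    path: str
    chain: str
    label: str | None = None

    def resolved_label(self) -> str:
        return self.label or f"{Path(self.path).stem}:{self.chain}"


@dataclass
class RunConfig:
    """Configuration of one analysis run; defaults follow the study setup
    (0.1 A bins, 4 A SRO cutoff, 5-7 A signal window, 7 A shell)."""

    index: StructureInput
    variants: list[StructureInput] = field(default_factory=list)
    bin_size: float = 0.1
    sro_cutoff: float = 4.0
    window: tuple[float, float] = (5.0, 7.0)
    shell_cutoff: float = 7.0
    tolerance: float = 0.05
    selectors: list[str] = field(default_factory=lambda: ["total", "C-C"])
    scales: list[str] = field(default_factory=lambda: ["peptide"])
    protonate: bool = False
    deprotonate_phenols: bool = False
    outdir: str = "pepcoord_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bin_size <= 0 or self.sro_cutoff <= 0 or self.shell_cutoff <= 0:
            raise ValueError("bin_size and cutoffs must be positive")
        r1, r2 = self.window
        if not (0 <= r1 < r2):
            raise ValueError(f"bad signal window {self.window}")
        bad = set(self.scales) - {"peptide", "shell", "complex"}
        if bad:
            raise ValueError(f"unknown scales: {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        raw["index"] = StructureInput(**raw["index"])
        raw["variants"] = [StructureInput(**v) for v in raw.get("variants", [])]
        if "window" in raw:
            raw["window"] = tuple(raw["window"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = {
            "index": vars(self.index),
            "variants": [vars(v) for v in self.variants],
            "bin_size": self.bin_size,
            "sro_cutoff": self.sro_cutoff,
            "window": list(self.window),
            "shell_cutoff": self.shell_cutoff,
            "tolerance": self.tolerance,
            "selectors": list(self.selectors),
            "scales": list(self.scales),
            "protonate": self.protonate,
            "deprotonate_phenols": self.deprotonate_phenols,
            "outdir": self.outdir,
            "seed": self.seed,
        }
        return d


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_structure(inp: StructureInput, scale: str, cfg: RunConfig) -> StructureModel:
    label = inp.resolved_label()
    if scale == "peptide":
        s = read_pdb(inp.path, inp.chain, label=label)
        if cfg.protonate:
            scheme = ProtonationScheme(
                deprotonate_phenols=cfg.deprotonate_phenols
            )
            s = protonate(s, scheme)
        return s
    complex_model = read_pdb(inp.path, None, label=f"{Path(inp.path).stem}:all")
    if scale == "complex":
        return complex_model
    peptide = read_pdb(inp.path, inp.chain, label=label)
    return extract_environment(
        complex_model, peptide, cfg.shell_cutoff,
        label=f"{label}+shell{cfg.shell_cutoff:g}",
    )


def _infer_substituted_residue(index: StructureModel, variant: StructureModel) -> int | None:
    a, b = index.sequence(), variant.sequence()
    if len(a) != len(b):
        return None
    diffs = [i + 1 for i, (x, y) in enumerate(zip(a, b)) if x != y]
    return diffs[0] if len(diffs) == 1 else None


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage and write the report bundle; returns the report dict."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    curve_rows, profile_rows, delta_rows, sro_rows, group_rows = [], [], [], [], []
    report: dict = {"scales": {}, "version": __version__}

    for scale in cfg.scales:
        stage = f"load[{scale}]"
        try:
            structures = [
                (inp, _load_structure(inp, scale, cfg))
                for inp in [cfg.index, *cfg.variants]
            ]
        except PepcoordError as exc:
            raise PepcoordError(f"stage {stage} failed: {exc}") from exc
        index_model = structures[0][1]

        r_max = max(s.max_pair_distance() for _, s in structures)
        r_max = (np.floor(r_max / cfg.bin_size + 1e-9) + 1) * cfg.bin_size

        profiles: dict[tuple[str, str], object] = {}
        for inp, s in structures:
            props = bulk_properties(s)
            report.setdefault("structures", {})[f"{s.label}@{scale}"] = {
                "n_atoms": props.n_atoms,
                "volume_A3": props.volume,
                "rho0_atoms_per_A3": props.rho0,
                "mass_density_g_per_cm3": props.mass_density,
            }
            for selector in cfg.selectors:
                try:
                    h = build_histogram(s, selector, cfg.bin_size, r_max)
                except EmptySelectionError:
                    log.warning("selector %s empty for %s; skipped", selector, s.label)
                    continue
                pdf = pdf_from_histogram(h)
                rdf = rdf_from_pdf(pdf)
                prof = cumulative_profile(rdf)
                profiles[(s.label, selector)] = prof
                for kind, curve in (("PDF", pdf), ("RDF", rdf)):
                    curve_rows.extend(
                        {"scale": scale, "structure": s.label, "selector": selector,
                         "kind": kind, "r": r, "value": v}
                        for r, v in zip(curve.r_grid, curve.values)
                    )
                profile_rows.extend(
                    {"scale": scale, "structure": s.label, "selector": selector,
                     "r": r, "n_cum": v}
                    for r, v in zip(prof.r_grid, prof.n_cum)
                )
            for species in ("C", "N", "O"):
                try:
                    st = cluster_stats(s, species, cfg.sro_cutoff, cfg.bin_size)
                except EmptySelectionError:
                    continue
                sro_rows.append(
                    {"scale": scale, "structure": s.label, "central": species,
                     "cutoff": st.cutoff, "mean_cn": st.mean_cn,
                     "number_density": st.cluster_number_density,
                     "mass_density": st.cluster_mass_density,
                     "weighted_mean_distance": st.weighted_mean_distance}
                )

        scale_report: dict = {"calls": [], "contributions": []}
        calls = []
        for inp, s in structures[1:]:
            for selector in cfg.selectors:
                key_v, key_i = (s.label, selector), (index_model.label, selector)
                if key_v not in profiles or key_i not in profiles:
                    continue
                delta = coordination_delta(profiles[key_v], profiles[key_i])
                delta_rows.extend(
                    {"scale": scale, "variant": s.label, "index": index_model.label,
                     "selector": selector, "r": r, "delta": d}
                    for r, d in zip(delta.r_grid, delta.delta)
                )
                call = call_identity(delta, cfg.window, cfg.tolerance)
                scale_report["calls"].append(
                    {"variant": s.label, "selector": selector, "call": call.call,
                     "delta_at_limit": call.delta_at_limit,
                     "magnitude": call.magnitude}
                )
                if selector == "total":
                    calls.append(call)

        if scale == "peptide":
            for inp, s in structures[1:]:
                sub = _infer_substituted_residue(index_model, s)
                for selector in cfg.selectors:
                    if selector == "total":
                        continue
                    try:
                        table_i = group_coordination(index_model, selector, cfg.window)
                        table_v = group_coordination(s, selector, cfg.window)
                    except (EmptySelectionError, ValueError):
                        continue
                    for tbl in (table_i, table_v):
                        group_rows.extend(
                            {"scale": scale, "structure": tbl.label,
                             "selector": tbl.selector, "group": k,
                             "r1": tbl.window[0], "r2": tbl.window[1],
                             "coordination": v}
                            for k, v in sorted(tbl.entries.items())
                        )
                    if sub is None:
                        continue
                    try:
                        rep = contribution_percent(table_v, table_i, sub)
                    except DegenerateDeviationError:
                        continue
                    scale_report["contributions"].append(
                        {"variant": s.label, "selector": selector,
                         "substituted_residue": sub,
                         "percent": rep.percent_contribution,
                         "percent_abs": rep.percent_contribution_abs,
                         "total_deviation": rep.total_deviation}
                    )

        if calls:
            scale_report["ranking"] = [c.variant_label for c in rank_variants(calls)]
        report["scales"][scale] = scale_report

    frames = {
        "curves.csv": pd.DataFrame(curve_rows),
        "profiles.csv": pd.DataFrame(profile_rows),
        "deltas.csv": pd.DataFrame(delta_rows),
        "sro.csv": pd.DataFrame(sro_rows),
        "groups.csv": pd.DataFrame(group_rows),
    }
    for name, df in frames.items():
        df.to_csv(outdir / name, index=False, float_format=_FLOAT_FMT)

    manifest = {
        "config": cfg.to_dict(),
        "versions": {
            "pepcoord": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "inputs": {
            inp.path: _sha256(inp.path) for inp in [cfg.index, *cfg.variants]
        },
    }
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True).encode()
    ).hexdigest()
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
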