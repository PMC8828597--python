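"""Run configuration and end-to-end orchestration.

A run is described by one YAML/JSON mapping: the network topology (preset
name or explicit compartments/edges), per-group per-compartment input
files, an ordered comparison plan (control -> experimental pairs), the
presence threshold, the lipid classes to analyse and the marker panels.
The three analysis stages — traffic classification, Switch Analysis and
Abundance Analysis — are independently invokable; ``run_pipeline`` chains
them and writes a machine-readable manifest.  All CSV outputs are
byte-deterministic for identical config and inputs (the manifest, which
carries a timestamp, is the only file that differs between runs).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .abundance import BUNDLED_PANELS, MarkerPanel, enfc_table, panel_enfc
from .lipids import parse_lipid_name
from .network import PRESETS, CompartmentNetwork, build_network
from .presence import (
    PRESENCE_THRESHOLD,
    AbundanceTable,
    PresenceProfile,
    build_profile,
    read_abundance_csv,
)
from .plotting import radar_panel, susp_figure
from .susp import build_susp
from .switch import switch_analysis, switch_report
from .traffic import TrafficClassification, classify_traffic

logger = logging.getLogger("lipidtraffic")

__all__ = ["RunConfig", "load_config", "run_pipeline"]


class ConfigError(ValueError):
    """Raised for invalid run configurations."""


@dataclass
class RunConfig:
    """Validated run configuration."""

    network: CompartmentNetwork
    groups: dict[str, dict[str, Path]]  # group -> compartment -> input file
    comparisons: list[tuple[str, str]]  # (control, experimental)
    threshold: float = PRESENCE_THRESHOLD
    lipid_classes: tuple[str, ...] = ("TG", "PC", "SM")
    panels: tuple[MarkerPanel, ...] = tuple(BUNDLED_PANELS.values())
    susp_compartments: tuple[str, ...] = ("serum",)
    normalise: bool = True
    strict_pairs_only: bool = False
    seed: int = 0
    raw: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        declared = set(self.groups)
        for ctrl, expt in self.comparisons:
            for g in (ctrl, expt):
                if g not in declared:
                    raise ConfigError(
                        f"comparison {ctrl}->{expt} references undeclared "
                        f"group {g!r} (declared: {sorted(declared)})"
                    )
        comps = set(self.network.compartments)
        for group, files in self.groups.items():
            missing = comps - set(files)
            if missing:
                raise ConfigError(
                    f"group {group!r} lacks input files for compartment(s) "
                    f"{sorted(missing)}"
                )

    def config_hash(self) -> str:
        payload = json.dumps(self.raw, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _resolve_network(spec) -> CompartmentNetwork:
    if isinstance(spec, str):
        try:
            return PRESETS[spec]
        except KeyError:
            raise ConfigError(
                f"unknown network preset {spec!r}; available: {sorted(PRESETS)}"
            ) from None
    return build_network(spec)


def _resolve_panels(names) -> tuple[MarkerPanel, ...]:
    out = []
    for item in names:
        if isinstance(item, str):
            try:
                out.append(BUNDLED_PANELS[item])
            except KeyError:
                raise ConfigError(
                    f"unknown marker panel {item!r}; bundled: "
                    f"{sorted(BUNDLED_PANELS)}"
                ) from None
        else:
            out.append(
                MarkerPanel(
                    item["name"],
                    tuple(parse_lipid_name(n) for n in item["members"]),
                )
            )
    return tuple(out)


def load_config(path: str | Path, base_dir: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML/JSON run configuration file.

    Relative input paths are resolved against the config file's directory
    unless ``base_dir`` overrides it.
    """
    path = Path(path)
    base = Path(base_dir) if base_dir is not None else path.parent
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    network = _resolve_network(raw.get("network", "mouse-adult"))
    groups = {
        str(g): {str(c): (base / f) for c, f in files.items()}
        for g, files in raw.get("groups", {}).items()
    }
    comparisons = [tuple(pair) for pair in raw.get("comparisons", [])]
    kwargs = {}
    if "panels" in raw:
        kwargs["panels"] = _resolve_panels(raw["panels"])
    if "lipid_classes" in raw:
        kwargs["lipid_classes"] = tuple(raw["lipid_classes"])
    if "susp_compartments" in raw:
        kwargs["susp_compartments"] = tuple(raw["susp_compartments"])
    return RunConfig(
        network=network,
        groups=groups,
        comparisons=comparisons,
        threshold=float(raw.get("threshold", PRESENCE_THRESHOLD)),
        normalise=bool(raw.get("normalise", True)),
        strict_pairs_only=bool(raw.get("strict_pairs_only", False)),
        seed=int(raw.get("seed", 0)),
        raw=raw,
        **kwargs,
    )


def _read_group_tables(config: RunConfig, group: str) -> dict[str, AbundanceTable]:
    tables = {}
    for comp, path in config.groups[group].items():
        if not Path(path).exists():
            raise ConfigError(f"input file not found: {path} ({group}/{comp})")
        tables[comp] = read_abundance_csv(path, compartment=comp, phenotype=group)
    return tables


def compute_profiles(config: RunConfig) -> dict[str, PresenceProfile]:
    """Presence profiles for every declared group."""
    profiles = {}
    for group in sorted(config.groups):
        tables = _read_group_tables(config, group)
        profiles[group] = build_profile(tables.values(), config.threshold)
        n_present = sum(profiles[group].calls.values())
        logger.info(
            "%s: %d present calls over %d compartments",
            group,
            n_present,
            len(tables),
        )
    return profiles


def compute_classifications(
    config: RunConfig, profiles: Mapping[str, PresenceProfile]
) -> dict[str, TrafficClassification]:
    """U/A/B classification for every group (all configured classes)."""
    out = {}
    for group, profile in profiles.items():
        cls = classify_traffic(
            profile,
            config.network,
            lipid_class=None,
            strict_pairs_only=config.strict_pairs_only,
        )
        out[group] = cls
        logger.info("%s: category counts %s", group, cls.counts())
    return out


def run_pipeline(
    config: RunConfig,
    outdir: str | Path,
    stages: Sequence[str] = ("classify", "switch", "abundance", "susp"),
) -> dict[str, Path]:
    """Execute the requested stages and write all outputs under ``outdir``.

    Returns a mapping of output names to written paths.  ``stages`` allows
    any subset of the analyses to run on its own; presence calling always
    runs, as every stage depends on it.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    profiles = compute_profiles(config)

    presence_rows = []
    for group, profile in sorted(profiles.items()):
        for (comp, name), present in sorted(profile.calls.items()):
            presence_rows.append(
                {
                    "phenotype": group,
                    "compartment": comp,
                    "variable": name,
                    "detection_fraction": profile.detection_fraction[(comp, name)],
                    "present": int(present),
                }
            )
    presence_path = outdir / "presence_calls.csv"
    pd.DataFrame(presence_rows).to_csv(presence_path, index=False)
    written["presence"] = presence_path

    classifications: dict[str, TrafficClassification] = {}
    if {"classify", "switch"} & set(stages):
        classifications = compute_classifications(config, profiles)
    if "classify" in stages:
        frame = pd.concat(
            [c.to_frame() for _, c in sorted(classifications.items())],
            ignore_index=True,
        )
        path = outdir / "classification.csv"
        frame.to_csv(path, index=False)
        written["classification"] = path

    if "switch" in stages:
        results = []
        for ctrl, expt in config.comparisons:
            results.extend(
                switch_analysis(
                    classifications[ctrl],
                    classifications[expt],
                    comparison=f"{ctrl} vs {expt}",
                    lipid_classes=config.lipid_classes,
                )
            )
        report = switch_report(results)
        path = outdir / "switch_report.csv"
        report.to_csv(path, index=False)
        written["switch"] = path
        for _, row in report[report["category"] == "A"].iterrows():
            logger.info(
                "%s %s A-type %s J=%.2f p=%.2f",
                row["comparison"],
                row["lipid_class"],
                row["ratio"],
                row["J"],
                row["p"],
            )

    enfc_tables: dict[str, pd.DataFrame] = {}
    if {"abundance", "susp"} & set(stages):
        group_tables = {g: _read_group_tables(config, g) for g in sorted(config.groups)}
        for ctrl, expt in config.comparisons:
            label = f"{ctrl} vs {expt}"
            enfc_tables[label] = enfc_table(
                group_tables[ctrl],
                group_tables[expt],
                comparison=label,
                normalise=config.normalise,
                presence_threshold=config.threshold,
            )
    if "abundance" in stages:
        for label, table in enfc_tables.items():
            slug = label.replace(" ", "_")
            path = outdir / f"enfc_{slug}.csv"
            table.to_csv(path, index=False)
            written[f"enfc:{label}"] = path
        for panel in config.panels:
            panel_frames = []
            for ctrl, expt in config.comparisons:
                label = f"{ctrl} vs {expt}"
                panel_frames.append(
                    panel_enfc(
                        group_tables[ctrl],
                        group_tables[expt],
                        panel,
                        comparison=label,
                        normalise=config.normalise,
                        presence_threshold=config.threshold,
                    )
                )
            combined = pd.concat(panel_frames, ignore_index=True)
            csv_path = outdir / f"panel_{panel.name}.csv"
            combined.to_csv(csv_path, index=False)
            written[f"panel:{panel.name}"] = csv_path
            for member in panel.members:
                svg = outdir / f"radar_{panel.name}_{member.canonical_name.replace(':', '-')}.svg"
                radar_panel(panel_frames, member.canonical_name, svg)
                written[f"radar:{panel.name}:{member.canonical_name}"] = svg

    if "susp" in stages and len(config.comparisons) >= 2:
        (c1, e1), (c2, e2) = config.comparisons[0], config.comparisons[1]
        lab1, lab2 = f"{c1} vs {e1}", f"{c2} vs {e2}"
        for comp in config.susp_compartments:
            ds = build_susp(
                enfc_tables[lab1], enfc_tables[lab2], comp, lab1, lab2
            )
            slug = comp.replace(" ", "_")
            csv_path = outdir / f"susp_{slug}.csv"
            ds.to_frame().to_csv(csv_path, index=False)
            written[f"susp:{comp}"] = csv_path
            svg = outdir / f"susp_{slug}.svg"
            susp_figure(ds, svg)
            written[f"susp_fig:{comp}"] = svg

    manifest = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "stages": list(stages),
        "outputs": {k: str(v) for k, v in written.items()},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime()),
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    written["manifest"] = manifest_path
    return written
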