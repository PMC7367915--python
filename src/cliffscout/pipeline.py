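"""End-to-end orchestration: curate -> pairs -> thresholds -> detect ->
network -> reports, with a manifest recording inputs, configuration and
checksums so a run is reproducible bit-for-bit."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .cliffs import (
    class_profile,
    cliffs_table,
    detect_g1,
    detect_g2,
    detect_g3,
    detect_chirality_cliffs,
    detect_iso_acs,
    flag_privileged,
    summarize,
    summarize_global,
)
from .data_model import CurationConfig, MeasurementType, curate, read_activity_table, write_curated
from .mmp import PairConfig, pairs_for_class, pairs_table
from .multisite import analyze_all, quartet_table
from .network import build, classify_clusters, cluster_table, write_edge_list, write_graphml
from .thresholds import constant_threshold, profile_report

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Serializable description of one pipeline run."""

    input_path: str
    output_dir: str
    # similarity / pairs
    fingerprint: str = "ecfp4"
    rules: str = "retrosynthetic"
    k_max: int = 2
    max_substituent_atoms: int = 13
    min_core_ratio: float = 2.0
    max_substituent_size_diff: int = 8
    # potency criterion
    threshold_mode: str = "class"  # "class" | "constant"
    constant_threshold: float = 2.0
    min_pairs: int = 10
    # detection
    generation: int = 3
    flags: tuple[str, ...] = ()  # subset of {"iso", "chirality"}
    ps_smarts: tuple[str, ...] = ()
    # curation
    min_class_size: int = 100
    allowed_types: tuple[str, ...] = ("Ki",)
    spread_limit: float = 1.0
    # network
    hub_min_degree: int = 3
    seed: int = 0
    epsilon: float = 0.3

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        for key in ("flags", "ps_smarts", "allowed_types"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)

    def pair_config(self, k_max: int | None = None) -> PairConfig:
        return PairConfig(
            k_max=self.k_max if k_max is None else k_max,
            rules=self.rules,
            max_substituent_atoms=self.max_substituent_atoms,
            min_core_ratio=self.min_core_ratio,
            max_substituent_size_diff=self.max_substituent_size_diff,
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns the manifest (also written to the
    output directory).  Any stage failure marks the manifest and
    re-raises."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "versions": {
            "cliffscout": __version__,
            "python": sys.version.split()[0],
        },
        "inputs": {},
        "artifacts": [],
        "status": "running",
    }
    try:
        import rdkit

        manifest["versions"]["rdkit"] = rdkit.__version__
    except Exception:  # pragma: no cover
        pass

    def emit(name: str) -> Path:
        path = out / name
        manifest["artifacts"].append(name)
        return path

    try:
        inp = Path(config.input_path)
        manifest["inputs"][str(inp)] = _sha256(inp)

        records = read_activity_table(inp)
        curation = curate(
            records,
            CurationConfig(
                allowed_types=frozenset(
                    MeasurementType.coerce(t) for t in config.allowed_types
                ),
                spread_limit=config.spread_limit,
                min_class_size=config.min_class_size,
            ),
        )
        if not curation.classes:
            raise ValueError(
                "no activity class passed curation "
                f"(min_class_size={config.min_class_size})"
            )
        write_curated(curation, emit("curated.csv"), emit("curation_log.json"))

        all_pairs, profiles, all_acs, summaries, contexts = [], [], [], [], []
        for cls in curation.classes:
            pcfg = config.pair_config()
            pairs = pairs_for_class(cls, curation.structures, pcfg)
            all_pairs.append(pairs_table(pairs, cls.target_id))

            ss_pairs = [p for p in pairs if p.n_sites == 1]
            if config.threshold_mode == "class":
                profile = class_profile(
                    cls, curation.structures, pairs=ss_pairs,
                    min_pairs=config.min_pairs, fallback=config.constant_threshold,
                )
            else:
                profile = constant_threshold(config.constant_threshold, cls.target_id)
            profiles.append(profile)

            if config.generation == 1:
                criterion = (
                    f"fp_{config.fingerprint}" if config.fingerprint in ("maccs", "ecfp4")
                    else "mmp"
                )
                acs = detect_g1(
                    cls, curation.structures, criterion=criterion,
                    threshold=config.constant_threshold,
                    qps=ss_pairs if criterion == "mmp" else None,
                )
                n_qp = len(ss_pairs) if criterion == "mmp" else None
            elif config.generation == 2:
                acs = detect_g2(cls, curation.structures, profile=profile, qps=ss_pairs)
                n_qp = len(ss_pairs)
            else:
                acs = detect_g3(cls, curation.structures, profile=profile, qps=pairs)
                n_qp = len(pairs)

            extra_threshold = (
                profile if config.threshold_mode == "class" else config.constant_threshold
            )
            if "iso" in config.flags:
                acs = list(acs) + detect_iso_acs(
                    cls, curation.structures, threshold=extra_threshold
                )
            if "chirality" in config.flags:
                acs = list(acs) + detect_chirality_cliffs(
                    cls, curation.structures, threshold=extra_threshold
                )
            if config.ps_smarts:
                acs = flag_privileged(acs, config.ps_smarts, curation.structures)

            all_acs.extend(acs)
            if n_qp is not None:
                summaries.append(summarize(acs, n_qp, cls))
            contexts.extend(
                analyze_all(
                    [a for a in acs if a.n_sites == 2],
                    cls, curation.structures, epsilon=config.epsilon,
                    threshold=profile.threshold if profile.threshold else config.constant_threshold,
                )
            )

        import pandas as pd

        pd.concat(all_pairs, ignore_index=True).to_csv(emit("pairs.csv"), index=False)
        profile_report(profiles).to_csv(emit("thresholds.csv"), index=False)
        cliffs_table(all_acs).to_csv(emit("cliffs.csv"), index=False)
        quartet_table(contexts, config.epsilon).to_csv(emit("multisite.csv"), index=False)

        if all_acs:
            net = build(all_acs, multi_target=True)
            write_edge_list(net, emit("network_edges.tsv"))
            write_graphml(net, emit("network.graphml"))
            cluster_table(classify_clusters(net, config.hub_min_degree)).to_csv(
                emit("clusters.csv"), index=False
            )

        summary = {
            "per_class": [
                {
                    "target_id": s.target_id,
                    "n_compounds": s.n_compounds,
                    "n_qp": s.n_qp,
                    "n_ac": s.n_ac,
                    "pct_ac": s.pct_ac,
                    "n_ac_compounds": s.n_ac_compounds,
                    "pct_ac_compounds": s.pct_ac_compounds,
                    "n_ss_ac": s.n_ss_ac,
                    "n_ds_ac": s.n_ds_ac,
                }
                for s in summaries
            ],
            "global": summarize_global(summaries) if summaries else None,
        }
        emit("summary.json").write_text(json.dumps(summary, indent=1))

        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["error"] = str(exc)
        manifest["checksums"] = {
            name: _sha256(out / name) for name in manifest["artifacts"] if (out / name).exists()
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise
    manifest["checksums"] = {name: _sha256(out / name) for name in manifest["artifacts"]}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
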