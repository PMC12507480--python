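"""End-to-end orchestration: generate -> analyze -> summarize.

A run takes a :class:`RunConfig`, simulates the configured cohort, pushes
every recording through the dynamic and static analyses (and optionally the
large-strain trilinear fit), writes tidy per-sample CSVs, a summary table,
the serialized config, and a manifest with SHA-256 checksums of every
artifact.  One failed sample is logged and excluded, never fatal.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dma as dma_mod
from . import neutral_zone as nz_mod
from . import ssa as ssa_mod
from .stats import build_summary
from .synthetic import (
    default_branches_for,
    generate_cohort,
    make_dma_protocol,
    make_ssa_protocol,
    simulate_response,
)
from .types import CohortConfig, Geometry, ViscoParams
from .waveform import write_waveform

logger = logging.getLogger("afshear")

__all__ = ["RunConfig", "run"]


@dataclass
class RunConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    seed: int = 0
    run_dma: bool = True
    run_ssa: bool = True
    run_nz: bool = False
    dma_sampling_rate_hz: float = 100.0
    ssa_sampling_rate_hz: float = 50.0
    ssa_hold_s: float = 1200.0
    noise_sd_n: float = 0.01
    save_waveforms: bool = False
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = {
            "seed": self.seed,
            "run_dma": self.run_dma,
            "run_ssa": self.run_ssa,
            "run_nz": self.run_nz,
            "dma_sampling_rate_hz": self.dma_sampling_rate_hz,
            "ssa_sampling_rate_hz": self.ssa_sampling_rate_hz,
            "ssa_hold_s": self.ssa_hold_s,
            "noise_sd_n": self.noise_sd_n,
            "save_waveforms": self.save_waveforms,
            "log_level": self.log_level,
            "cohort": {
                "rank_rho": self.cohort.rank_rho,
                "seed": self.cohort.seed,
                "stratified": self.cohort.stratified,
                "groups": [vars(g) for g in self.cohort.groups],
            },
        }
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        from .types import GroupConfig

        d = yaml.safe_load(Path(path).read_text()) or {}
        cohort_d = d.pop("cohort", None)
        cohort = CohortConfig()
        if cohort_d:
            groups = tuple(GroupConfig(**g) for g in cohort_d.pop("groups", []))
            if not groups:
                groups = CohortConfig().groups
            cohort = CohortConfig(groups=groups, **cohort_d)
        return cls(cohort=cohort, **d)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run(config: RunConfig, outdir: str | Path) -> Path:
    """Execute the configured pipeline; returns the artifact directory."""
    logging.basicConfig(level=config.log_level)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.yaml").write_text(yaml.safe_dump(config.to_dict()))

    cohort = CohortConfig(
        groups=config.cohort.groups,
        rank_rho=config.cohort.rank_rho,
        seed=config.seed,
        stratified=config.cohort.stratified,
    )
    samples = generate_cohort(cohort)
    geometry = Geometry()
    rng = np.random.default_rng(config.seed + 1)

    ssa_rows, dma_rows, nz_rows = [], [], []
    for sample in samples:
        try:
            params = ViscoParams(
                g_eq_kpa=sample.true_g_eq_kpa,
                branches=default_branches_for(sample.true_g_eq_kpa),
                noise_sd_n=config.noise_sd_n,
                seed=config.seed,
            )
            base = {
                "sample_id": sample.sample_id,
                "group": sample.group,
                "orientation": sample.orientation,
                "true_g_eq_kpa": sample.true_g_eq_kpa,
                "true_thickness_um": sample.true_thickness_um,
            }
            if config.run_ssa:
                protocol = make_ssa_protocol(
                    hold_s=config.ssa_hold_s,
                    sampling_rate_hz=config.ssa_sampling_rate_hz,
                )
                rec = simulate_response(params, protocol, geometry, rng=rng)
                if config.save_waveforms:
                    write_waveform(rec, outdir / f"{sample.sample_id}-ssa.csv")
                res = ssa_mod.analyze_ssa(rec)
                row = dict(base)
                row.update(
                    modulus_kpa=res.modulus_kpa,
                    intercept_kpa=res.intercept_kpa,
                    r_squared=res.r_squared,
                )
                for lvl, rel in zip(res.strain_levels, res.relaxation_kpa):
                    row[f"relaxation_{lvl * 100:.3g}pct_kpa"] = rel
                ssa_rows.append(row)
            if config.run_dma:
                protocol = make_dma_protocol(
                    10.0, sampling_rate_hz=config.dma_sampling_rate_hz
                )
                rec = simulate_response(params, protocol, geometry, rng=rng)
                if config.save_waveforms:
                    write_waveform(rec, outdir / f"{sample.sample_id}-dma.csv")
                for res in dma_mod.analyze_dma(rec):
                    row = dict(base)
                    row.update(
                        frequency_hz=res.frequency_hz,
                        hysteresis_uj=res.hysteresis_uj,
                        tan_delta=res.tan_delta,
                        g_storage_kpa=res.g_storage_kpa,
                        g_loss_kpa=res.g_loss_kpa,
                        g_dynamic_kpa=res.g_dynamic_kpa,
                        phase_reliable=res.phase_reliable,
                    )
                    dma_rows.append(row)
            if config.run_nz:
                protocol = make_dma_protocol(
                    40.0, sampling_rate_hz=config.dma_sampling_rate_hz
                )
                rec = simulate_response(params, protocol, geometry, rng=rng)
                # linear solid: large-strain loop stays linear, so the
                # trilinear fit degenerates by design; record the outcome
                try:
                    fits = nz_mod.fit_cycle(rec, seg_label="1Hz")
                    for name, fit in fits.items():
                        nz_rows.append(
                            dict(
                                base,
                                curve=name,
                                nz_stiffness_n_mm=fit.nz_stiffness_n_mm,
                                cz_stiffness_n_mm=fit.cz_stiffness_n_mm,
                                tz_stiffness_n_mm=fit.tz_stiffness_n_mm,
                                nz_length_mm=fit.nz_length_mm,
                            )
                        )
                except nz_mod.DegenerateFitError as exc:
                    nz_rows.append(dict(base, curve="degenerate", note=str(exc)))
        except Exception:
            logger.exception("sample %s failed; excluded", sample.sample_id)

    artifacts = [outdir / "config.yaml"]
    if ssa_rows:
        df = pd.DataFrame(ssa_rows)
        df.to_csv(outdir / "ssa_results.csv", index=False)
        artifacts.append(outdir / "ssa_results.csv")
        summary = build_summary(df, value_cols=["modulus_kpa"])
        summary.to_csv(outdir / "ssa_summary.csv", index=False)
        artifacts.append(outdir / "ssa_summary.csv")
    if dma_rows:
        pd.DataFrame(dma_rows).to_csv(outdir / "dma_results.csv", index=False)
        artifacts.append(outdir / "dma_results.csv")
    if nz_rows:
        pd.DataFrame(nz_rows).to_csv(outdir / "nz_results.csv", index=False)
        artifacts.append(outdir / "nz_results.csv")
    artifacts.extend(sorted(outdir.glob("*-ssa.csv")))
    artifacts.extend(sorted(outdir.glob("*-dma.csv")))
    artifacts.extend(sorted(outdir.glob("*.json")))

    manifest = {
        str(p.relative_to(outdir)): _sha256(p) for p in artifacts if p.exists()
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return outdir
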