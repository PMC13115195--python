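"""The docking model and its results.

:class:`MultiLigandDocking` bundles a receptor model, one or more rigid
ligand copies and a run configuration; :meth:`MultiLigandDocking.fit`
executes the staged protocol — propose rigid-body poses, discard
steric overlaps, score every accepted pose, retain the K lowest binding
energies, cluster them — and returns a :class:`DockingResults` object
carrying the ranked poses, the energy clusters, per-stage counts and a
``summary()`` table.  Interaction analysis, refinement-job emission and
thermodynamics hang off the results object.

The whole fit is a pure function of ``(receptor, ligands, config,
seed)``: identical inputs give byte-identical result tables.  Proposals
are processed in batches purely for memory reasons; retention merges by
``(energy, proposal id)`` so the outcome is independent of batching.
"""

from __future__ import annotations

import hashlib
import json
import logging
import subprocess
import tempfile
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .clash import ClashCriterion, clash_mask_batch
from .cluster import EnergyClusters, RankedPoseSet, TopKSelector, cluster_by_energy
from .contacts import ContactSpec, contact_table
from .energy import EnergyResult, SurrogateParams, score_surrogate_batch
from .engines import ThermoRecord, parse_output, write_input
from .sampling import SamplingRegion, apply_pose_batch, propose_batch, \
    region_from_model
from .structure import ActiveSiteModel, Molecule, extract_active_site, \
    read_ligand, read_pdb, write_pdb

logger = logging.getLogger("ringdock")

__all__ = ["DockingConfig", "RunConfig", "MultiLigandDocking",
           "DockingResults", "RunSummary", "run_docking",
           "emit_refinement_jobs", "collect_refinement"]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class DockingConfig:
    """In-memory engine settings (no file paths).

    ``n_proposals`` defaults to the protocol's production scale of one
    million Monte Carlo proposals per simulation; desk-scale runs set it
    far lower.
    """

    n_proposals: int = 1_000_000
    seed: int = 0
    region: SamplingRegion | None = None  # None: auto box, pad -2 Å
    clash: ClashCriterion = field(default_factory=ClashCriterion)
    surrogate: SurrogateParams = field(default_factory=SurrogateParams)
    backend: str = "surrogate"  # "surrogate" | "mopac" | "gaussian"
    engine_executable: str | None = None
    k_retain: int = 1000
    linkage: str = "single"
    cut: str = "gap"
    n_clusters: int | None = None
    batch_size: int = 4096

    def validate(self) -> None:
        if self.n_proposals < 1:
            raise ValueError("n_proposals must be >= 1")
        if self.k_retain < 1:
            raise ValueError("k_retain must be >= 1")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.backend not in ("surrogate", "mopac", "gaussian"):
            raise ValueError(f"unknown backend {self.backend!r}")
        if self.backend != "surrogate":
            if not self.engine_executable:
                raise ValueError(
                    f"backend {self.backend!r} needs engine_executable"
                )
            if not Path(self.engine_executable).exists():
                raise FileNotFoundError(
                    f"engine executable not found: {self.engine_executable}"
                )


@dataclass
class RunConfig:
    """File-level run description (what the CLI reads from YAML)."""

    receptor: str
    ligands: list[str]
    output: str
    residues: list[tuple[str, int]] | None = None
    copies: int = 1
    docking: DockingConfig = field(default_factory=DockingConfig)
    contacts: list[ContactSpec] = field(default_factory=list)
    refine_dialect: str = "mopac"

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        dock_keys = {f for f in DockingConfig.__dataclass_fields__}
        dock_kwargs = {k: v for k, v in raw.items() if k in dock_keys}
        if "region" in dock_kwargs and dock_kwargs["region"] is not None:
            r = dock_kwargs["region"]
            dock_kwargs["region"] = SamplingRegion(
                center=tuple(r["center"]), shape=r.get("shape", "box"),
                half_extents=tuple(r["half_extents"])
                if "half_extents" in r else None,
                radius=r.get("radius"),
            )
        if "clash" in raw:
            dock_kwargs["clash"] = ClashCriterion(**raw["clash"])
        if "surrogate" in raw:
            s = dict(raw["surrogate"])
            base = SurrogateParams()
            dock_kwargs["surrogate"] = SurrogateParams(
                epsilon={**base.epsilon, **s.get("epsilon", {})},
                sigma={**base.sigma, **s.get("sigma", {})},
                charges=s.get("charges", {}),
                dielectric=float(s.get("dielectric", 1.0)),
                cutoff=float(s.get("cutoff", 12.0)),
            )
        specs = [
            ContactSpec(
                residue=(c["residue"][0], int(c["residue"][1])),
                residue_atom_selector=c.get("residue_atom", "any"),
                ligand_atom_selector=c.get("ligand_atom", "any"),
                strong_cutoff=float(c.get("cutoff", 3.2)),
            )
            for c in raw.get("contacts", [])
        ]
        return RunConfig(
            receptor=raw["receptor"],
            ligands=list(raw["ligands"]),
            output=raw.get("output", "dock_out"),
            residues=[(n, int(i)) for n, i in raw["residues"]]
            if raw.get("residues") else None,
            copies=int(raw.get("copies", 1)),
            docking=DockingConfig(**dock_kwargs),
            contacts=specs,
            refine_dialect=raw.get("refine_dialect", "mopac"),
        )

    def validate(self) -> None:
        for p in [self.receptor, *self.ligands]:
            if not Path(p).exists():
                raise FileNotFoundError(f"input file not found: {p}")
        if self.copies < 1:
            raise ValueError("copies must be >= 1")
        self.docking.validate()


# ---------------------------------------------------------------------------
# Summary record
# ---------------------------------------------------------------------------

@dataclass
class RunSummary:
    """Per-stage accounting of one docking run."""

    generated: int
    accepted: int
    rejected: int
    best_energy: float | None
    n_retained: int
    n_clusters: int
    seed: int
    backend: str
    wall_time_s: float

    def __post_init__(self) -> None:
        if self.generated != self.accepted + self.rejected:
            raise ValueError("generated != accepted + rejected")
        if min(self.generated, self.accepted, self.rejected) < 0:
            raise ValueError("negative counts")


# ---------------------------------------------------------------------------
# Engine-backed scoring (out-of-process)
# ---------------------------------------------------------------------------

class _EngineScorer:
    """Scores species by writing a deck, invoking the external engine and
    parsing its output.  Used only when an engine backend is configured;
    the surrogate path never shells out."""

    def __init__(self, dialect: str, executable: str):
        self.dialect = dialect
        self.executable = executable

    def score(self, parts: Sequence) -> EnergyResult:
        deck = write_input(parts, task="single_point", dialect=self.dialect)
        with tempfile.TemporaryDirectory() as tmp:
            inp = Path(tmp) / "job.in"
            out = Path(tmp) / "job.out"
            inp.write_text(deck)
            with open(out, "w") as fh:
                subprocess.run([self.executable, str(inp)], stdout=fh,
                               check=True)
            result, _ = parse_output(out.read_text(), dialect=self.dialect)
        return result


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

class MultiLigandDocking:
    """Rigid-body Monte Carlo docking of one or more ligand copies into a
    truncated active-site model.

    Parameters
    ----------
    receptor : frozen active-site model (or any Molecule).
    ligands : the rigid ligand copies to dock simultaneously — one
        entry per copy; two copies of the same molecule model dual
        occupancy.
    config : engine settings; ``None`` uses defaults (which include the
        production-scale proposal count — override for desk-scale runs).
    """

    def __init__(self, receptor: ActiveSiteModel | Molecule,
                 ligands: Sequence[Molecule],
                 config: DockingConfig | None = None):
        if not ligands:
            raise ValueError("need at least one ligand copy")
        for lig in ligands:
            if not lig.rigid:
                raise ValueError(
                    f"ligand {lig.name!r} must be rigid (rigid=True)"
                )
        self.receptor = receptor
        self.ligands = list(ligands)
        self.config = config or DockingConfig()
        self.config.validate()

    @property
    def n_ligands(self) -> int:
        return len(self.ligands)

    # -- fitting ----------------------------------------------------------

    def fit(self, seed: int | None = None) -> "DockingResults":
        """Run sample → clash filter → score → retain → cluster."""
        cfg = self.config
        cfg.validate()
        used_seed = cfg.seed if seed is None else int(seed)
        t0 = time.perf_counter()
        region = cfg.region or region_from_model(self.receptor)
        rng = np.random.default_rng(used_seed)
        logger.info("docking: %d proposals, %d ligand(s), seed=%d, backend=%s",
                    cfg.n_proposals, self.n_ligands, used_seed, cfg.backend)

        crit = cfg.clash
        rec_coords = self.receptor.coords
        rec_elements = self.receptor.elements
        rec_radii = crit.radii_for(rec_elements)
        if not crit.include_hydrogens:
            keep = np.array([e.upper() != "H" for e in rec_elements])
            rec_coords_cl, rec_radii_cl = rec_coords[keep], rec_radii[keep]
        else:
            rec_coords_cl, rec_radii_cl = rec_coords, rec_radii
        lig_coords0 = [lig.coords for lig in self.ligands]
        lig_radii = []
        lig_keep = []
        for lig in self.ligands:
            radii = crit.radii_for(lig.elements)
            if not crit.include_hydrogens:
                k = np.array([e.upper() != "H" for e in lig.elements])
            else:
                k = np.ones(len(lig.atoms), dtype=bool)
            lig_keep.append(k)
            lig_radii.append(radii[k])

        surr = cfg.surrogate
        rec_arrays = (rec_coords, *surr.atom_arrays(self.receptor))
        lig_params = [surr.atom_arrays(lig) for lig in self.ligands]
        engine = None
        e_site, e_lig = 0.0, [0.0] * self.n_ligands
        if cfg.backend != "surrogate":
            engine = _EngineScorer(cfg.backend, cfg.engine_executable)
            e_site = engine.score([self.receptor]).energy
            e_lig = [engine.score([lig]).energy for lig in self.ligands]

        selector = TopKSelector(cfg.k_retain)
        generated = accepted = 0
        remaining = cfg.n_proposals
        next_pose_id = 0
        while remaining > 0:
            nb = min(cfg.batch_size, remaining)
            trans, quats = propose_batch(region, self.n_ligands, nb, rng)
            placed = [
                apply_pose_batch(lig_coords0[j], trans[:, j], quats[:, j])
                for j in range(self.n_ligands)
            ]
            clash = clash_mask_batch(
                rec_coords_cl, rec_radii_cl,
                [placed[j][:, lig_keep[j], :] for j in range(self.n_ligands)],
                lig_radii, crit.scale,
            )
            ok = np.flatnonzero(~clash)
            generated += nb
            accepted += ok.size
            if ok.size:
                if engine is None:
                    e_complex = score_surrogate_batch(
                        rec_arrays, [placed[j][ok] for j in range(self.n_ligands)],
                        lig_params, surr,
                    )
                else:
                    e_complex = np.array([
                        engine.score(
                            [self.receptor] + [
                                self.ligands[j].with_coords(placed[j][i])
                                for j in range(self.n_ligands)
                            ]
                        ).energy
                        for i in ok
                    ])
                e_bind = e_complex - e_site - sum(e_lig)
                pose_ids = next_pose_id + ok
                payloads = [
                    (trans[i].copy(), quats[i].copy(),
                     float(e_complex[k]))
                    for k, i in enumerate(ok)
                ]
                selector.update(pose_ids.tolist(), e_bind.tolist(), payloads)
            next_pose_id += nb
            remaining -= nb
            if generated % (50 * cfg.batch_size) < cfg.batch_size:
                logger.info("  %d/%d proposals, %d accepted",
                            generated, cfg.n_proposals, accepted)

        ranked = selector.result()
        clusters = cluster_by_energy(
            ranked.energies, linkage=cfg.linkage, cut=cfg.cut,
            k=cfg.n_clusters,
        ) if len(ranked) else None
        wall = time.perf_counter() - t0
        summary = RunSummary(
            generated=generated, accepted=accepted,
            rejected=generated - accepted,
            best_energy=float(ranked.energies[0]) if len(ranked) else None,
            n_retained=len(ranked),
            n_clusters=clusters.n_clusters if clusters else 0,
            seed=used_seed, backend=cfg.backend, wall_time_s=wall,
        )
        logger.info("done: %d accepted / %d generated, best %.3f kJ/mol",
                    accepted, generated, summary.best_energy or np.nan)
        return DockingResults(model=self, ranked=ranked, clusters=clusters,
                              run_summary=summary, region=region,
                              seed=used_seed)


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------

class DockingResults:
    """Fitted docking run: ranked poses, clusters, counts, tables."""

    def __init__(self, model: MultiLigandDocking, ranked: RankedPoseSet,
                 clusters: EnergyClusters | None, run_summary: RunSummary,
                 region: SamplingRegion, seed: int):
        self.model = model
        self.ranked = ranked
        self.clusters = clusters
        self.run_summary = run_summary
        self.region = region
        self.seed = seed

    # -- reconstruction ---------------------------------------------------

    def placed_ligands(self, entry_index: int) -> list[Molecule]:
        """Rebuild the placed ligand copies of one retained entry."""
        trans, quats, _ = self.ranked.entries[entry_index].payload
        out = []
        for j, lig in enumerate(self.model.ligands):
            coords = apply_pose_batch(lig.coords, trans[None, j], quats[None, j])
            out.append(lig.with_coords(coords[0]))
        return out

    def representative_complex(self, cluster_label: int = 1
                               ) -> tuple[list[Molecule], float]:
        """Placed ligands and binding energy of a cluster representative."""
        if self.clusters is None:
            raise ValueError("no clusters (empty result)")
        idx = self.clusters.representatives[cluster_label]
        return self.placed_ligands(idx), float(self.ranked.energies[idx])

    # -- tables -----------------------------------------------------------

    def cluster_table(self) -> pd.DataFrame:
        """Pose id, energies, cluster label and representative flag for
        every retained pose."""
        n = len(self.ranked)
        labels = self.clusters.labels if self.clusters is not None \
            else np.zeros(n, dtype=int)
        reps = set(self.clusters.representatives.values()) \
            if self.clusters is not None else set()
        return pd.DataFrame(
            {
                "pose_id": [e.pose_id for e in self.ranked.entries],
                "binding_energy_kJ_mol": self.ranked.energies,
                "complex_energy_kJ_mol": [e.payload[2]
                                          for e in self.ranked.entries],
                "cluster": labels,
                "representative": [i in reps for i in range(n)],
            }
        )

    def contact_table(self, specs: Sequence[ContactSpec],
                      cluster_label: int = 1) -> pd.DataFrame:
        """Interaction distances for a cluster representative."""
        ligands, _ = self.representative_complex(cluster_label)
        return contact_table(self.model.receptor, ligands, specs)

    def summary(self) -> str:
        """Plain-text run summary in a fixed layout."""
        s = self.run_summary
        lines = [
            "Rigid-body Monte Carlo docking results",
            "=" * 46,
            f"ligand copies:        {self.model.n_ligands}"
            f"  ({', '.join(l.name or '?' for l in self.model.ligands)})",
            f"receptor atoms:       {len(self.model.receptor.atoms)}",
            f"backend:              {s.backend}",
            f"seed:                 {s.seed}",
            f"proposals generated:  {s.generated}",
            f"accepted (no clash):  {s.accepted}",
            f"rejected (clash):     {s.rejected}",
            f"retained (top-K):     {s.n_retained}",
            f"energy clusters:      {s.n_clusters}",
        ]
        if s.best_energy is not None:
            lines.append(f"best binding energy:  {s.best_energy:.3f} kJ/mol")
        if self.clusters is not None:
            lines.append("-" * 46)
            lines.append("cluster  size  representative E (kJ/mol)")
            for lab, idx in self.clusters.representatives.items():
                size = int(np.sum(self.clusters.labels == lab))
                lines.append(
                    f"{lab:>7d}  {size:>4d}  {self.ranked.energies[idx]:.3f}"
                )
        return "\n".join(lines)

    # -- persistence ------------------------------------------------------

    def save(self, outdir: str | Path,
             contact_specs: Sequence[ContactSpec] = ()) -> None:
        """Write result tables, representative complexes, the summary and
        a resumable checkpoint into ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.cluster_table().to_csv(outdir / "clusters.csv", index=False,
                                    float_format="%.6f")
        if contact_specs and self.clusters is not None:
            self.contact_table(list(contact_specs)).to_csv(
                outdir / "contacts.csv", index=False, float_format="%.3f")
        if self.clusters is not None:
            for lab in self.clusters.representatives:
                ligands, _ = self.representative_complex(lab)
                write_pdb([Molecule(atoms=self.model.receptor.atoms,
                                    name="receptor")] + ligands,
                          outdir / f"representative_cluster{lab}.pdb",
                          remark=f"cluster {lab} representative")
        s = asdict(self.run_summary)
        s["wall_time_s"] = round(s["wall_time_s"], 3)
        (outdir / "summary.json").write_text(json.dumps(s, indent=2) + "\n")
        (outdir / "summary.txt").write_text(self.summary() + "\n")
        self._write_checkpoint(outdir / "checkpoint.json")

    def _config_hash(self) -> str:
        cfg = self.model.config
        blob = json.dumps({
            "n_proposals": cfg.n_proposals, "seed": self.seed,
            "k": cfg.k_retain, "backend": cfg.backend,
            "clash_scale": cfg.clash.scale,
            "n_ligands": self.model.n_ligands,
            "region": [list(self.region.center),
                       self.region.shape,
                       list(self.region.half_extents or []),
                       self.region.radius],
        }, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def _write_checkpoint(self, path: Path) -> None:
        data = {
            "config_hash": self._config_hash(),
            "seed": self.seed,
            "generated": self.run_summary.generated,
            "accepted": self.run_summary.accepted,
            "entries": [
                {
                    "pose_id": e.pose_id,
                    "binding_energy": e.energy,
                    "complex_energy": e.payload[2],
                    "translations": e.payload[0].tolist(),
                    "quaternions": e.payload[1].tolist(),
                }
                for e in self.ranked.entries
            ],
        }
        path.write_text(json.dumps(data) + "\n")

    @staticmethod
    def load_checkpoint(model: MultiLigandDocking, path: str | Path
                        ) -> "DockingResults":
        """Rebuild results from a sampling-stage checkpoint: clustering
        and analysis are recomputed, sampling is not."""
        from .cluster import ScoredPose

        data = json.loads(Path(path).read_text())
        entries = [
            ScoredPose(
                pose_id=e["pose_id"],
                payload=(np.asarray(e["translations"]),
                         np.asarray(e["quaternions"]),
                         e["complex_energy"]),
                energy=e["binding_energy"],
            )
            for e in data["entries"]
        ]
        ranked = RankedPoseSet(entries=entries, k=model.config.k_retain)
        clusters = cluster_by_energy(
            ranked.energies, linkage=model.config.linkage,
            cut=model.config.cut, k=model.config.n_clusters,
        ) if len(ranked) else None
        summary = RunSummary(
            generated=data["generated"], accepted=data["accepted"],
            rejected=data["generated"] - data["accepted"],
            best_energy=float(ranked.energies[0]) if len(ranked) else None,
            n_retained=len(ranked),
            n_clusters=clusters.n_clusters if clusters else 0,
            seed=data["seed"], backend=model.config.backend, wall_time_s=0.0,
        )
        region = model.config.region or region_from_model(model.receptor)
        res = DockingResults(model=model, ranked=ranked, clusters=clusters,
                             run_summary=summary, region=region,
                             seed=data["seed"])
        if res._config_hash() != data["config_hash"]:
            raise ValueError("checkpoint does not match the current config")
        return res


# ---------------------------------------------------------------------------
# File-level orchestration
# ---------------------------------------------------------------------------

def run_docking(config: RunConfig, *, resume: bool = True
                ) -> tuple[RunSummary, DockingResults]:
    """End-to-end run from a file-level config: read inputs, build the
    model, fit (or resume from a matching checkpoint), save outputs."""
    config.validate()
    chains = read_pdb(config.receptor)
    if config.residues:
        receptor = extract_active_site(chains, config.residues,
                                       source_id=config.receptor)
    else:
        atoms = [a for m in chains for a in m.atoms]
        receptor = ActiveSiteModel(
            atoms=atoms,
            residue_index=_index_by_residue(atoms),
            source_id=config.receptor,
        )
    ligands: list[Molecule] = []
    for path in config.ligands:
        ligands.append(read_ligand(path))
    if len(ligands) == 1 and config.copies > 1:
        ligands = ligands * config.copies
    model = MultiLigandDocking(receptor, ligands, config.docking)

    outdir = Path(config.output)
    ckpt = outdir / "checkpoint.json"
    results: DockingResults | None = None
    if resume and ckpt.exists():
        try:
            results = DockingResults.load_checkpoint(model, ckpt)
            logger.info("resumed from checkpoint %s (sampling skipped)", ckpt)
        except ValueError:
            logger.warning("checkpoint mismatch; re-running sampling")
    if results is None:
        results = model.fit()
    results.save(outdir, contact_specs=config.contacts)
    return results.run_summary, results


def _index_by_residue(atoms) -> dict[int, list[int]]:
    index: dict[int, list[int]] = {}
    for i, a in enumerate(atoms):
        num = a.residue_number if a.residue_number is not None else 1
        index.setdefault(num, []).append(i)
    return index


def emit_refinement_jobs(results: DockingResults, outdir: str | Path,
                         dialect: str = "mopac") -> pd.DataFrame:
    """One optimise+frequency input deck per retained pose, with the
    frozen-atom convention (receptor heavy frozen, receptor H free,
    ligand free); returns the manifest mapping deck file → pose id."""
    if not len(results.ranked):
        raise ValueError("no retained poses to refine")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, entry in enumerate(results.ranked.entries):
        ligands = results.placed_ligands(i)
        deck = write_input([results.model.receptor] + ligands,
                           task="optimize+freq", dialect=dialect,
                           title=f"pose {entry.pose_id} refinement")
        fname = f"refine_{i:05d}.{'mop' if dialect == 'mopac' else 'gjf'}"
        (outdir / fname).write_text(deck)
        rows.append({"deck": fname, "pose_id": entry.pose_id,
                     "binding_energy_kJ_mol": entry.energy})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.csv", index=False,
                    float_format="%.6f")
    return manifest


def collect_refinement(paths: Sequence[str | Path], *,
                       dialect: str | None = None
                       ) -> tuple[list[ThermoRecord], list[str]]:
    """Parse refinement outputs into thermochemistry records.

    Returns ``(records, failures)`` where failures lists files that were
    truncated or non-converged (they are excluded from the records).
    All-failed or empty input is an error.
    """
    if not paths:
        raise ValueError("no engine output files given")
    records: list[ThermoRecord] = []
    failures: list[str] = []
    for p in paths:
        p = Path(p)
        try:
            result, thermo = parse_output(p.read_text(), dialect=dialect,
                                          species_id=p.stem)
        except ValueError:
            failures.append(str(p))
            continue
        if not result.converged:
            failures.append(str(p))
            continue
        records.append(thermo if thermo is not None
                       else ThermoRecord(species_id=p.stem,
                                         dHf=result.energy))
    if not records:
        raise ValueError(
            f"all {len(paths)} engine outputs were non-converged"
        )
    return records, failures
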