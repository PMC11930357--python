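"""File formats, pipeline configuration and the end-to-end driver.

Ensembles travel as multi-MODEL CA-trace PDB files (read/written through
biotite); profiles as ATSAS-style 3-column ASCII (q, I, sigma; '#' comments;
2-column files are accepted with sigma marked absent). ``run_pipeline``
reproduces the full analysis flow on synthetic data: generate -> per-snapshot
Debye -> iterative BME -> theta scan -> contact maps -> weighted clustering ->
Guinier / P(r) / Dmax -> GA selection, writing every artifact plus a
machine-readable manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

from .core import Conformer, Ensemble, ScatteringProfile, Selection

logger = logging.getLogger("ensaxs")

__all__ = [
    "read_ensemble_pdb",
    "write_ensemble_pdb",
    "read_profile_dat",
    "write_profile_dat",
    "PipelineConfig",
    "run_pipeline",
]


# ---------------------------------------------------------------------------
# PDB ensembles


def write_ensemble_pdb(ensemble: Ensemble, path) -> None:
    """Write a multi-MODEL CA-trace PDB (one bead per residue)."""
    topo = ensemble.topology
    n = topo.n_beads
    atoms = bst.AtomArray(n)
    atoms.coord = topo.coords
    atoms.chain_id = topo.chain_ids
    atoms.res_id = topo.residue_ids
    atoms.res_name = np.full(n, "GLY", dtype="U5")
    atoms.atom_name = np.full(n, "CA", dtype="U6")
    atoms.element = np.full(n, "C", dtype="U2")
    atoms.hetero = np.zeros(n, dtype=bool)
    stack = bst.stack([atoms] * len(ensemble))
    stack.coord = ensemble.coords_array()
    f = PDBFile()
    f.set_structure(stack)
    f.write(str(path))


def _scan_model_atom_counts(path) -> list[int]:
    counts, current, in_model = [], 0, False
    with open(path) as fh:
        for line in fh:
            rec = line[:6].strip()
            if rec == "MODEL":
                in_model, current = True, 0
            elif rec == "ENDMDL":
                counts.append(current)
                in_model = False
            elif rec == "ATOM" and line[12:16].strip() == "CA":
                current += 1
    if not counts and current:
        counts.append(current)  # single implicit model
    return counts


def read_ensemble_pdb(path) -> Ensemble:
    """Read a multi-MODEL CA-trace PDB into an Ensemble (uniform weights).

    Scattering weights default to 1 and charges to 0; they are model inputs,
    not PDB content.
    """
    counts = _scan_model_atom_counts(path)
    if len(set(counts)) > 1:
        bad = next(i for i, c in enumerate(counts, start=1) if c != counts[0])
        raise ValueError(
            f"inconsistent topology across models in {path}: model {bad} has "
            f"{counts[bad - 1]} CA atoms, model 1 has {counts[0]}"
        )
    f = PDBFile.read(str(path))
    stack = f.get_structure(model=None)
    stack = stack[:, stack.atom_name == "CA"]
    conformers = [
        Conformer(
            coords=stack.coord[m],
            residue_ids=stack.res_id,
            chain_ids=stack.chain_id,
        )
        for m in range(stack.stack_depth())
    ]
    return Ensemble(conformers=conformers, source=str(path))


# ---------------------------------------------------------------------------
# .dat profiles


def write_profile_dat(profile: ScatteringProfile, path, header: str = "") -> None:
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        fh.write("# q[A^-1]  I  sigma\n")
        sig = profile.sigma
        for i in range(len(profile)):
            if sig is None:
                fh.write(f"{profile.q[i]:.8e} {profile.I[i]:.8e}\n")
            else:
                fh.write(f"{profile.q[i]:.8e} {profile.I[i]:.8e} {sig[i]:.8e}\n")


def read_profile_dat(path) -> ScatteringProfile:
    """Read a 3-column (q, I, sigma) or 2-column (sigma absent) ASCII profile."""
    data = np.loadtxt(path, comments="#", ndmin=2)
    if data.shape[0] < 2:
        raise ValueError("profile needs at least 2 numeric rows")
    if data.shape[1] < 2:
        raise ValueError("profile needs at least 2 columns (q, I)")
    q, I = data[:, 0], data[:, 1]
    sigma = data[:, 2] if data.shape[1] >= 3 else None
    if np.any(np.diff(q) <= 0):
        raise ValueError("q must be strictly increasing")
    return ScatteringProfile(q=q, I=I, sigma=sigma, metadata={"source": str(path)})


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class PipelineConfig:
    """Desk-scale configuration of the full synthetic analysis pipeline."""

    outdir: str = "ensaxs_out"
    # synthetic system
    system: str = "delta_csd"        # "delta_csd" | "hp1a_dimer"
    phosphorylated: bool = True
    n_molecules: int = 1
    n_conformers: int = 120
    fractions: tuple[float, ...] = (0.7, 0.3)
    kappas: tuple[float, ...] = (5.0, 0.0)
    seed: int = 0
    noise_frac: float = 0.01
    # q grid
    q_min: float = 0.01
    q_max: float = 0.30
    n_q: int = 60
    # reweighting
    theta: float | None = None       # None -> L-curve elbow from the scan
    theta_grid: tuple[float, ...] = tuple(np.geomspace(0.1, 1e4, 12))
    # structure analysis
    contact_cutoff: float = 11.0
    cluster_cutoff: float = 20.0
    top_k: int = 6
    # GA
    ga_k: int = 20
    ga_population: int = 60
    ga_generations: int = 80

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("fractions", "kappas", "theta_grid"):
            if key in raw:
                raw[key] = tuple(float(v) for v in raw[key])
        return cls(**raw)

    def validate(self) -> None:
        if self.system not in ("delta_csd", "hp1a_dimer"):
            raise ValueError("system must be 'delta_csd' or 'hp1a_dimer'")
        if len(self.fractions) != len(self.kappas):
            raise ValueError("fractions and kappas must have equal length")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")
        if self.n_q < 2 or self.q_min <= 0 or self.q_max <= self.q_min:
            raise ValueError("invalid q grid")


def _stage(name):
    logger.info("stage: %s", name)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis flow; returns the manifest dict."""
    from . import __version__
    from .bme import MaxEntReweighting
    from .debye import ensemble_profiles
    from .ga import GAConfig, distribution_report, ensemble_metric, ga_select
    from .profiles import dmax_scan, guinier_fit, pr_from_coordinates
    from .structure import (
        contact_probability,
        gromos_cluster_weighted,
        representative_structures,
    )
    from .synthetic import (
        MixtureSpec,
        Subpopulation,
        delta_csd_topology,
        hp1a_dimer_topology,
        make_mixture_ensemble,
        make_target_profile,
    )
    from .core import Selection

    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "version": __version__, "outputs": {}}

    def record(key: str, path: Path):
        manifest["outputs"][key] = str(path)

    try:
        _stage("synthetic ensemble")
        if config.system == "hp1a_dimer":
            topo = hp1a_dimer_topology(phosphorylated=config.phosphorylated)
        else:
            topo = delta_csd_topology(
                phosphorylated=config.phosphorylated,
                n_molecules=config.n_molecules,
            )
        spec = MixtureSpec(
            topology=topo,
            subpopulations=tuple(
                Subpopulation(f"pop{i}", k) for i, k in enumerate(config.kappas)
            ),
            fractions=config.fractions,
            n_conformers=config.n_conformers,
            seed=config.seed,
        )
        ensemble, labels = make_mixture_ensemble(spec)
        p = out / "ensemble.pdb"
        write_ensemble_pdb(ensemble, p)
        record("ensemble_pdb", p)
        truth = {
            "labels": labels.tolist(),
            "fractions": list(config.fractions),
            "kappas": list(config.kappas),
            "seed": config.seed,
        }
        p = out / "ground_truth.json"
        p.write_text(json.dumps(truth, indent=1))
        record("ground_truth", p)

        _stage("target profile")
        q = np.geomspace(config.q_min, config.q_max, config.n_q)
        w_true = np.zeros(len(ensemble))
        fr = np.asarray(config.fractions)
        counts = np.bincount(labels, minlength=fr.size)
        for j, lab in enumerate(labels):
            w_true[j] = fr[lab] / counts[lab]
        target = make_target_profile(
            ensemble, w_true, q, noise_frac=config.noise_frac, seed=config.seed
        )
        p = out / "target.dat"
        write_profile_dat(target, p, header="synthetic target profile")
        record("target_dat", p)

        _stage("per-snapshot SAXS (Debye)")
        I = ensemble_profiles(ensemble, target.q)

        _stage("theta scan")
        model = MaxEntReweighting(I, target, ensemble=ensemble)
        scan = model.theta_scan(np.asarray(config.theta_grid))
        p = out / "theta_scan.tsv"
        scan.table().to_csv(p, sep="\t", index=False)
        record("theta_scan", p)
        theta = config.theta if config.theta is not None else scan.select_elbow()

        _stage("iterative BME")
        result = model.fit_iterative(theta)
        reweighted = ensemble.with_weights(result.weights)
        p = out / "weights.tsv"
        result.weight_table().to_csv(p, sep="\t", index=False, float_format="%.10e")
        record("weights", p)
        p = out / "reweight.json"
        d = result.to_dict()
        d["theta_source"] = "config" if config.theta is not None else "lcurve_elbow"
        d["history"] = result.history
        p.write_text(json.dumps(d, indent=1))
        record("reweight", p)

        _stage("contact maps")
        cm_intra = contact_probability(
            reweighted, cutoff=config.contact_cutoff, mode="intra"
        )
        p = out / "contact_intra.tsv"
        cm_intra.to_frame().to_csv(p, sep="\t")
        record("contact_intra", p)
        if len(ensemble.topology.chains) == 2:
            cm_inter = contact_probability(
                reweighted, cutoff=config.contact_cutoff, mode="inter"
            )
            p = out / "contact_inter.tsv"
            cm_inter.to_frame().to_csv(p, sep="\t")
            record("contact_inter", p)

        _stage("weighted clustering")
        n_chain = len(ensemble.topology.chains)
        rmsd_ranges = [(11, 14), (19, 74), (89, 91), (102, 107)]
        if config.system == "hp1a_dimer":
            # superpose on the CSD core; RMSD set includes it
            sup = Selection.from_ranges([(113, 173)], role="superpose")
            rmsd_ranges.append((113, 173))
        else:
            sup = Selection.from_ranges([(19, 74)], role="superpose")
        rmsd_sel = Selection.from_ranges(rmsd_ranges, role="rmsd")
        assignment = gromos_cluster_weighted(
            reweighted,
            superpose_sel=sup,
            rmsd_sel=rmsd_sel,
            cutoff=config.cluster_cutoff,
            chain_swap=n_chain == 2,
        )
        p = out / "clusters.tsv"
        assignment.table().to_csv(p, sep="\t", index=False)
        record("clusters", p)
        reps = representative_structures(assignment, reweighted,
                                         top_k=min(config.top_k, assignment.n_clusters))
        rep_ens = Ensemble(
            conformers=[r[0] for r in reps],
            weights=np.full(len(reps), 1.0 / len(reps)),
        )
        p = out / "representatives.pdb"
        write_ensemble_pdb(rep_ens, p)
        record("representatives", p)

        _stage("Guinier / P(r) / Dmax")
        gu = guinier_fit(target, qrg_limit=1.3)
        p = out / "guinier.json"
        p.write_text(json.dumps(gu.to_dict(), indent=1))
        record("guinier", p)
        pr = pr_from_coordinates(reweighted, r_bin=2.0)
        p = out / "pr.dat"
        np.savetxt(p, np.column_stack([pr.r, pr.p]),
                   header="r[A]  P(r), reweighted ensemble")
        record("pr", p)
        cands = np.linspace(0.6 * pr.dmax, 1.3 * pr.dmax, 8)
        dmax_est, dtable = dmax_scan(target, cands)
        p = out / "dmax_scan.tsv"
        dtable.to_csv(p, sep="\t", index=False)
        record("dmax_scan", p)

        _stage("GA sub-ensemble selection")
        ga_conf = GAConfig(
            k=config.ga_k,
            population=config.ga_population,
            generations=config.ga_generations,
            seed=config.seed,
        )
        ga = ga_select(I, target, ga_conf)
        p = out / "ga_selected.tsv"
        np.savetxt(p, ga.indices, fmt="%d", header="selected pool indices")
        record("ga_selected", p)
        metr = ensemble_metric(ensemble, "dmax")
        dist = distribution_report(metr, ga.indices, metric="dmax")
        p = out / "ga_dmax_distributions.tsv"
        dist.table().to_csv(p, sep="\t", index=False)
        record("ga_distributions", p)

        manifest["summary"] = {
            "theta": float(theta),
            "chi2": result.chi2,
            "chi2_reduced": result.chi2_reduced,
            "phi_eff": result.phi_eff,
            "n_clusters": int(assignment.n_clusters),
            "guinier_rg": gu.rg,
            "dmax_estimate": float(dmax_est),
            "ga_chi2": ga.chi2,
        }
    except Exception as err:
        manifest["error"] = str(err)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        logger.error("pipeline aborted: %s", err)
        raise
    p = out / "manifest.json"
    p.write_text(json.dumps(manifest, indent=1))
    record_path = str(p)
    logger.info("pipeline complete; manifest at %s", record_path)
    return manifest
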