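"""Aggregated views and pipeline orchestration.

Contact maps count in-window interaction events in a matrix of ligand
oxygen classes (sulfate SO4-, carboxylate COO-, ring oxygen O, hydroxyl O3,
glycosidic O13/O14, ...) against receptor amino-acid types, separately for
direct hydrogen bonds and for water bridges. Binding-site summaries reduce
the same events to the receptor subdomains involved, flagging the most
contacted one. :func:`run_pipeline` chains the full analysis
(fixture -> stability -> interactions -> bridges -> energetics -> maps ->
summaries) with a provenance log and deterministic outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    AnalysisParams,
    ConfigError,
    DomainScheme,
    Trajectory,
    assign_domain,
)
from . import bridges as bridges_mod
from . import energetics as energetics_mod
from . import interactions as interactions_mod
from . import stability as stability_mod
from . import synthetic as synthetic_mod

__all__ = [
    "OXYGEN_CLASS_ROWS",
    "AMINO_ACID_COLUMNS",
    "ContactMatrix",
    "contact_map",
    "BindingSiteSummary",
    "binding_site_summary",
    "run_pipeline",
    "PipelineError",
]

logger = logging.getLogger(__name__)

#: Fixed contact-map row order: ligand oxygen classes plus the amide
#: nitrogen and a catch-all bucket.
OXYGEN_CLASS_ROWS = (
    "SO4-", "COO-", "O", "O3", "O13", "O14", "O4S", "O6S", "O7", "N", "other",
)

AMINO_ACID_COLUMNS = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

SUBDOMAIN_ORDER = ("IA", "IB", "IIA", "IIB", "IIIA", "IIIB")


class PipelineError(Exception):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class ContactMatrix:
    """Counts of in-window events per (ligand class, receptor residue type).

    ``matrix`` is a DataFrame with the fixed class rows and amino-acid
    columns; metadata records the interaction kind, window and solution
    species the counts were taken from.
    """

    matrix: pd.DataFrame
    kind: str
    window: tuple[float, float]
    solution: str = ""

    @property
    def total(self) -> int:
        return int(self.matrix.to_numpy().sum())


def _ligand_class(system, atom: int) -> str:
    cls = system.oxygen_class[atom]
    if cls is not None:
        return cls
    if system.elements[atom] == "N":
        return "N"
    logger.warning("ligand atom %d has no oxygen class; counted as 'other'", atom)
    return "other"


def contact_map(
    events: pd.DataFrame,
    system,
    kind: str,
    params: AnalysisParams | None = None,
    rows=OXYGEN_CLASS_ROWS,
    columns=AMINO_ACID_COLUMNS,
    solution: str = "",
) -> ContactMatrix:
    """Aggregate event records into a (ligand class x amino acid) count matrix.

    ``events`` is a record table from the interaction scan (``kind="HBo"``,
    endpoint columns ``receptor_atom``/``ligand_atom``) or the bridge scan
    (``kind="water_bridge"``, endpoint columns ``receptor_endpoint``/
    ``ligand_endpoint``); each in-window event contributes one count to the
    (ligand-endpoint class, receptor-endpoint residue type) cell.
    """
    params = params or AnalysisParams()
    window = (params.equilibration_time, params.window_end)
    matrix = pd.DataFrame(
        np.zeros((len(rows), len(columns)), dtype=int),
        index=list(rows), columns=list(columns),
    )
    if kind == "HBo":
        sub = events[events["type"] == "HBo"]
        rec_col, lig_col = "receptor_atom", "ligand_atom"
    elif kind == "water_bridge":
        sub = events[events["kind"] == "water"]
        rec_col, lig_col = "receptor_endpoint", "ligand_endpoint"
    else:
        raise ValueError("kind must be 'HBo' or 'water_bridge'")
    sub = sub[(sub["time_ps"] > window[0]) & (sub["time_ps"] <= window[1])]
    for row in sub.itertuples():
        rec_atom = int(getattr(row, rec_col))
        lig_atom = int(getattr(row, lig_col))
        cls = _ligand_class(system, lig_atom)
        if cls not in matrix.index:
            cls = "other"
        res = str(system.residue_names[rec_atom])
        if res not in matrix.columns:
            continue
        matrix.loc[cls, res] += 1
    return ContactMatrix(matrix=matrix, kind=kind, window=window,
                         solution=solution)


@dataclass
class BindingSiteSummary:
    """Receptor subdomains contacted over the analysis window.

    ``site_string`` lists, hyphenated and in canonical order
    (IA < IB < IIA < IIB < IIIA < IIIB), every subdomain with at least one
    event; ``strongest`` holds the maximal-count subdomain(s) (multiple on
    ties, with a logged warning). Residues outside the scheme accumulate
    under ``unassigned`` in ``counts`` but never enter the site string.
    """

    counts: dict[str, int]
    site_string: str
    strongest: tuple[str, ...]


def binding_site_summary(
    events: pd.DataFrame,
    system,
    scheme: DomainScheme | None = None,
    params: AnalysisParams | None = None,
    endpoint_column: str = "receptor_atom",
) -> BindingSiteSummary:
    """Count in-window events per receptor subdomain and flag the strongest.

    By default the metric is the plain event count of the passed records
    (direct interactions: HBo + HP + ionic).
    """
    params = params or AnalysisParams()
    if scheme is None:
        n_res = int(system.metadata.get("n_receptor_residues", 585))
        scheme = DomainScheme().scaled(n_res)
    sub = events[
        (events["time_ps"] > params.equilibration_time)
        & (events["time_ps"] <= params.window_end)
    ]
    counts: dict[str, int] = {}
    for atom in sub[endpoint_column].astype(int):
        label = assign_domain(int(system.residue_indices[atom]), scheme)
        counts[label] = counts.get(label, 0) + 1
    present = [s for s in SUBDOMAIN_ORDER if counts.get(s, 0) > 0]
    site_string = "-".join(present)
    strongest: tuple[str, ...] = ()
    if present:
        best = max(counts.get(s, 0) for s in present)
        strongest = tuple(s for s in present if counts[s] == best)
        if len(strongest) > 1:
            logger.warning("binding-site tie between %s", "-".join(strongest))
    return BindingSiteSummary(counts=counts, site_string=site_string,
                              strongest=strongest)


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

KNOWN_STAGES = ("stability", "interactions", "bridges", "energetics",
                "maps", "summaries")


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(path.read_bytes())
    return digest.hexdigest()


class _StageWriter:
    """Writes stage outputs to ``<name>.partial`` and finalizes on success."""

    def __init__(self, outdir: Path):
        self.outdir = outdir
        self.pending: list[Path] = []

    def path(self, name: str) -> Path:
        p = self.outdir / f"{name}.partial"
        self.pending.append(p)
        return p

    def finalize(self) -> list[str]:
        final = []
        for p in self.pending:
            target = p.with_name(p.name.removesuffix(".partial"))
            p.replace(target)
            final.append(target.name)
        self.pending.clear()
        return final


def _synthesize_energy_terms(traj: Trajectory, params: AnalysisParams,
                             seed: int) -> pd.DataFrame:
    """Deterministic toy component-energy table for fixture pipelines.

    The complex potential energy drifts down to a plateau (binding
    strengthens, then equilibrates) with seeded Gaussian noise; the
    separated-solute terms stay constant. Solvation terms use single-frame
    SASA of the separated solutes and the complex at the configured cost.
    """
    rng = np.random.default_rng(seed)
    n = traj.n_frames
    t = traj.times
    system = traj.system
    solute = np.concatenate([
        system.partition_indices("receptor"), system.partition_indices("ligand")
    ])
    _, area_r = energetics_mod.sasa(
        system, traj.frames[0], params.sasa_probe_radius,
        params.sasa_n_points, atom_indices=system.partition_indices("receptor"),
    )
    _, area_l = energetics_mod.sasa(
        system, traj.frames[0], params.sasa_probe_radius,
        params.sasa_n_points, atom_indices=system.partition_indices("ligand"),
    )
    _, area_c = energetics_mod.sasa(
        system, traj.frames[0], params.sasa_probe_radius,
        params.sasa_n_points, atom_indices=solute,
    )
    esr = energetics_mod.solvation_energy(area_r, params.sasa_cost)
    esl = energetics_mod.solvation_energy(area_l, params.sasa_cost)
    esc = energetics_mod.solvation_energy(area_c, params.sasa_cost)
    t_eq = params.equilibration_time
    approach = np.clip(t / max(t_eq, 1.0), 0.0, 1.0)
    epc = -250000.0 - 1500.0 * approach + 50.0 * rng.standard_normal(n)
    return pd.DataFrame({
        "time_ps": t,
        "Epr": np.full(n, -180000.0),
        "Epl": np.full(n, -68000.0),
        "Esr": np.full(n, esr),
        "Esl": np.full(n, esl),
        "Epc": epc,
        "Esc": np.full(n, esc),
    })


def run_pipeline(config: dict | str | Path, output_dir=None) -> dict:
    """Run the configured stages end-to-end; returns the summary payload.

    ``config`` is a mapping (or a YAML file path) with sections:

    * ``fixture``: :class:`~gaginter.synthetic.FixtureSpec` fields, with
      ``planted_events`` as ``[type, start, stop]`` triples and an optional
      ``desk_scale: true`` flag;
    * ``params``: :class:`~gaginter.core.AnalysisParams` fields;
    * ``stages``: ordered subset of ``stability, interactions, bridges,
      energetics, maps, summaries``;
    * ``energy_table``: optional path to a component-energy TSV (otherwise
      a deterministic synthetic table is generated);
    * ``output_dir``, ``seed``.

    Outputs are TSV/JSON files plus a provenance log; a stage failure
    aborts with the stage name, leaving that stage's ``.partial`` files.
    Re-running the same config reproduces identical summaries.
    """
    if not isinstance(config, dict):
        import yaml

        config = yaml.safe_load(Path(config).read_text())
    config = dict(config)
    stages = list(config.get("stages", KNOWN_STAGES))
    unknown = [s for s in stages if s not in KNOWN_STAGES]
    if unknown:
        raise ConfigError(f"unknown stages: {unknown}")
    outdir = Path(output_dir or config.get("output_dir", "gaginter_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))

    params = AnalysisParams(**config.get("params", {}), rng_seed=seed) \
        if "rng_seed" not in config.get("params", {}) \
        else AnalysisParams(**config.get("params", {}))

    fixture_cfg = dict(config.get("fixture", {}))
    desk = fixture_cfg.pop("desk_scale", True)
    raw_events = fixture_cfg.pop("planted_events", [])
    events = tuple(
        synthetic_mod.EventSpec(e[0], int(e[1]), int(e[2]))
        if not isinstance(e, synthetic_mod.EventSpec) else e
        for e in raw_events
    )
    fixture_cfg["planted_events"] = events
    fixture_cfg.setdefault("rng_seed", seed)
    spec = (
        synthetic_mod.FixtureSpec.desk_scale(**fixture_cfg) if desk
        else synthetic_mod.FixtureSpec(**fixture_cfg)
    )

    summary: dict = {"stages": stages, "seed": seed}
    outputs: dict[str, list[str]] = {}
    records = None
    bridge_records = None

    writer = _StageWriter(outdir)
    try:
        stage = "fixture"
        traj, ledger = synthetic_mod.generate_trajectory(spec, params)
        from .core import write_trajectory

        traj_path = writer.path("trajectory.pdb")
        write_trajectory(traj, traj_path)
        ledger.write_tsv(writer.path("ledger.tsv"))
        outputs[stage] = writer.finalize()
        summary["fixture"] = {
            "n_atoms": traj.system.n_atoms,
            "n_frames": traj.n_frames,
            "isomer": spec.ligand_isomer,
            "n_events": len(ledger),
        }

        for stage in stages:
            if stage == "stability":
                series = stability_mod.rmsd_series(traj)
                series.to_csv(writer.path("rmsd.tsv"), sep="\t", index=False)
                profile = stability_mod.rmsf(traj, params)
                profile.per_atom.to_csv(
                    writer.path("rmsf.tsv"), sep="\t", index=False
                )
                summary["stability"] = {
                    "rmsd_window_mean": interactions_mod.window_stats(
                        series["rmsd"].to_numpy(), traj.times, params
                    )["mean"],
                    "rmsf_group_sums": {
                        k: round(v, 6)
                        for k, v in sorted(profile.group_sums.items())
                    },
                }
            elif stage == "interactions":
                result = interactions_mod.census(traj, params)
                records = result.records
                records.to_csv(
                    writer.path("interactions.tsv"), sep="\t", index=False
                )
                summary["interactions"] = result.summary
            elif stage == "bridges":
                result = bridges_mod.bridge_census(traj, params)
                bridge_records = result.records
                bridge_records.to_csv(
                    writer.path("bridges.tsv"), sep="\t", index=False
                )
                summary["bridges"] = result.summary
            elif stage == "energetics":
                table_path = config.get("energy_table")
                if table_path is None:
                    terms = _synthesize_energy_terms(traj, params, seed)
                    synthetic_mod.generate_energy_table(
                        terms, writer.path("energy_terms.tsv")
                    )
                else:
                    terms = energetics_mod.read_energy_table(table_path)
                series = energetics_mod.series_from_table(
                    terms, solvation_cost=params.sasa_cost
                )
                pd.DataFrame({"time_ps": series.times, "eob": series.eob}).to_csv(
                    writer.path("eob.tsv"), sep="\t", index=False
                )
                stats = energetics_mod.window_average(series, params)
                stats["solvation_cost"] = params.sasa_cost
                summary["energetics"] = stats
            elif stage == "maps":
                if records is None:
                    records = interactions_mod.scan_trajectory(traj, params)
                if bridge_records is None:
                    bridge_records = bridges_mod.scan_bridges(traj, params)
                hbo_map = contact_map(records, traj.system, "HBo", params,
                                      solution=spec.cation_species)
                wb_map = contact_map(bridge_records, traj.system,
                                     "water_bridge", params,
                                     solution=spec.cation_species)
                hbo_map.matrix.to_csv(writer.path("contact_map_hbo.tsv"), sep="\t")
                wb_map.matrix.to_csv(
                    writer.path("contact_map_water_bridge.tsv"), sep="\t"
                )
                _render_heatmap(hbo_map, writer.path("contact_map_hbo.png"))
                _render_heatmap(wb_map, writer.path("contact_map_water_bridge.png"))
                summary["maps"] = {
                    "hbo_total": hbo_map.total,
                    "water_bridge_total": wb_map.total,
                }
            elif stage == "summaries":
                if records is None:
                    records = interactions_mod.scan_trajectory(traj, params)
                site = binding_site_summary(records, traj.system, params=params)
                summary["binding_site"] = {
                    "counts": dict(sorted(site.counts.items())),
                    "site_string": site.site_string,
                    "strongest": list(site.strongest),
                    "metric": "event_count(HBo+HP+ionic)",
                }
            outputs[stage] = writer.finalize()
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    provenance = {
        "seed": seed,
        "params": {k: v for k, v in sorted(vars(params).items())},
        "fixture": {
            "n_receptor_residues": spec.n_receptor_residues,
            "ligand_isomer": spec.ligand_isomer,
            "n_mers": spec.n_mers,
            "n_frames": spec.resolved_n_frames,
            "jitter_sigma": spec.jitter_sigma,
            "cation_species": spec.cation_species,
        },
        "input_hashes": {"trajectory.pdb": _sha256(outdir / "trajectory.pdb")},
        "outputs": outputs,
    }
    summary["provenance"] = provenance
    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=float)
    )
    (outdir / "provenance.json").write_text(
        json.dumps(provenance, indent=2, sort_keys=True, default=float)
    )
    return summary


def _render_heatmap(cmatrix: ContactMatrix, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    data = cmatrix.matrix.to_numpy()
    im = ax.imshow(data, aspect="auto", cmap="viridis")
    ax.set_xticks(range(len(cmatrix.matrix.columns)),
                  cmatrix.matrix.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(len(cmatrix.matrix.index)),
                  cmatrix.matrix.index, fontsize=7)
    ax.set_title(f"{cmatrix.kind} contacts ({cmatrix.solution})", fontsize=9)
    fig.colorbar(im, ax=ax, label="events")
    fig.tight_layout()
    fig.savefig(path, dpi=120, format="png")
    plt.close(fig)
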