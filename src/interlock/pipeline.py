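"""End-to-end orchestration: simulate -> coevolve -> psn -> interface -> metrics.

Every stage writes plain TSV files whose header comments record the config
hash, so a rerun with the same config and seed is byte-identical.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from . import coevolution as coev
from . import interface as iface
from . import metrics as met
from . import network as psn
from . import synthetic_data as synth
from .config import (
    ConfigError,
    RunConfig,
    parse_int_list,
    parse_pair_list,
    parse_residue_id,
)
from .structio import (
    Ensemble,
    Msa,
    read_fasta_alignment,
    read_pdb,
    write_fasta_alignment,
    write_pdb,
)

__all__ = ["run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    pass


def _fmt(value) -> str:
    if isinstance(value, float):
        return f"{value:.6f}"
    if isinstance(value, tuple):  # residue key
        return f"{value[0]}{value[1]}{value[2]}"
    return str(value)


def _write_tsv(
    path: Path,
    config_sha: str,
    columns: Sequence[str],
    rows: Iterable[Sequence],
) -> None:
    lines = [f"# config_sha256: {config_sha}", "\t".join(columns)]
    for row in rows:
        lines.append("\t".join(_fmt(v) for v in row))
    path.write_text("\n".join(lines) + "\n")


def _network_params(config: RunConfig) -> psn.NetworkParams:
    return psn.NetworkParams(
        contact_cutoff=config.get_float("network", "contact_cutoff"),
        i_min=config.get_float("network", "i_min"),
        exclude_neighbors=config.get_int("network", "exclude_neighbors"),
    )


def _energy_params(config: RunConfig) -> iface.EnergyParams:
    return iface.EnergyParams(
        e_hb=config.get_float("interface", "e_hb"),
        e_elec=config.get_float("interface", "e_elec"),
        elec_cutoff=config.get_float("interface", "elec_cutoff"),
        e_vdw=config.get_float("interface", "e_vdw"),
        vdw_lo=config.get_float("interface", "vdw_lo"),
        vdw_hi=config.get_float("interface", "vdw_hi"),
        interface_cutoff=config.get_float("interface", "interface_cutoff"),
        hotspot_threshold=config.get_float("interface", "hotspot_threshold"),
        hbond=iface.HBondCriteria(
            da_cutoff=config.get_float("interface", "da_cutoff"),
            angle_cutoff=config.get_float("interface", "angle_cutoff"),
        ),
    )


def _simulate(config: RunConfig, out: Path) -> None:
    seed = config.get_int("run", "seed")
    couplings = [
        synth.CouplingSpec(column_pair=(i, j), strength=s)
        for i, j, s in (
            (int(a), int(b), float(c))
            for a, b, c in (
                chunk.split(",")
                for chunk in config.get_str("synthetic", "couplings").split(";")
                if chunk.strip()
            )
        )
    ]
    msa_a, msa_b, truth = synth.generate_coupled_msa(
        n_seqs=config.get_int("synthetic", "n_seqs"),
        length_a=config.get_int("synthetic", "length_a"),
        length_b=config.get_int("synthetic", "length_b"),
        couplings=couplings,
        gap_fraction=config.get_float("synthetic", "gap_fraction"),
        seed=seed,
    )
    write_fasta_alignment(msa_a, out / "msa_a.fasta")
    write_fasta_alignment(msa_b, out / "msa_b.fasta")
    synth.write_ground_truth(truth, out / "msa_ground_truth.tsv")
    spec = synth.ToyComplexSpec(
        n_res_a=config.get_int("synthetic", "n_res_a"),
        n_res_b=config.get_int("synthetic", "n_res_b"),
        contact_pairs=parse_pair_list(config.get_str("synthetic", "contact_pairs")),
        hbond_pairs=parse_pair_list(config.get_str("synthetic", "hbond_pairs")),
        path_chain=parse_int_list(config.get_str("synthetic", "path_chain")),
    )
    complex_snap = synth.generate_toy_complex(spec, seed=seed)
    write_pdb(complex_snap, out / "complex.pdb")
    ensemble = synth.generate_ensemble(
        complex_snap,
        n_frames=config.get_int("synthetic", "n_frames"),
        noise_sd=config.get_float("synthetic", "noise_sd"),
        broken_fraction=config.get_float("synthetic", "broken_fraction"),
        seed=seed + 1,
    )
    write_pdb(ensemble, out / "ensemble.pdb")


def _resolve_msas(config: RunConfig, out: Path) -> tuple[Msa, Msa]:
    path_a = config.get("inputs", "msa_a") or str(out / "msa_a.fasta")
    path_b = config.get("inputs", "msa_b") or str(out / "msa_b.fasta")
    for p in (path_a, path_b):
        if not Path(p).exists():
            raise PipelineError(f"coevolve stage: missing alignment {p}")
    return read_fasta_alignment(path_a), read_fasta_alignment(path_b)


def _resolve_ensemble(config: RunConfig, out: Path, stage: str) -> Ensemble:
    path = config.get("inputs", "ensemble") or str(out / "ensemble.pdb")
    if not Path(path).exists():
        raise PipelineError(f"{stage} stage: missing ensemble {path}")
    return read_pdb(path)


def _coevolve(config: RunConfig, out: Path, summary: dict) -> None:
    msa_a, msa_b = _resolve_msas(config, out)
    result = coev.predict_coevolving_pairs(
        msa_a,
        msa_b,
        params=coev.PseudocountParams(
            a=config.get_float("coevolution", "a"),
            b=config.get_float("coevolution", "b"),
        ),
        top_n=config.get_int("coevolution", "top_n"),
        max_gap_fraction=config.get_float("coevolution", "max_gap_fraction"),
        min_separation=config.get_int("coevolution", "min_separation"),
        weighted=config.get_bool("coevolution", "weighted"),
    )
    _write_tsv(
        out / "pairs.tsv",
        config.sha256,
        ("i", "j", "mi", "mip", "rank", "class"),
        [(p.i, p.j, p.mi, p.mip, p.rank, p.pair_class) for p in result.pairs],
    )
    for cls in ("intra_A", "intra_B", "inter"):
        summary[f"pairs_{cls}"] = sum(1 for p in result.pairs if p.pair_class == cls)
    if result.pairs:
        top = result.pairs[0]
        summary["top_pair"] = f"{top.i},{top.j}"


def _psn(config: RunConfig, out: Path, summary: dict) -> None:
    ensemble = _resolve_ensemble(config, out, "psn")
    params = _network_params(config)
    if config.get_bool("network", "auto_imin"):
        profile = psn.largest_cluster_profile(ensemble[0], params=params)
        selected = psn.select_imin(profile)
        params.i_min = selected if selected is not None else 2.5
    stability = config.get_float("network", "stability")
    ens_net = psn.stable_network(ensemble, params, stability)
    _write_tsv(
        out / "edges.tsv",
        config.sha256,
        ("residue_1", "residue_2", "frequency", "stable"),
        [
            (u, v, f, int(f >= stability))
            for (u, v), f in sorted(ens_net.edge_frequency.items())
        ],
    )
    sources = [parse_residue_id(s) for s in config.get_list("network", "sources")]
    sink = parse_residue_id(config.get_str("network", "sink"))
    results = []
    rows = []
    for source in sources:
        res = psn.ensemble_paths(
            ensemble,
            source,
            sink,
            params,
            stability=stability,
            consensus_fraction=config.get_float("network", "consensus_fraction"),
        )
        results.append(res)
        for frame, path in enumerate(res.per_frame_paths):
            rows.append(
                (
                    _fmt(source),
                    _fmt(sink),
                    frame,
                    "-".join(_fmt(n) for n in path) if path else "NA",
                    (len(path) - 1) if path else "NA",
                )
            )
        summary[f"path_{_fmt(source)}_{_fmt(sink)}_avg_hops"] = (
            f"{res.average_length:.6f}" if res.average_length is not None else "NA"
        )
    _write_tsv(
        out / "paths.tsv",
        config.sha256,
        ("source", "sink", "frame", "path", "hops"),
        rows,
    )
    _write_tsv(
        out / "consensus.tsv",
        config.sha256,
        ("source", "sink", "consensus_nodes", "stable_network_path"),
        [
            (
                _fmt(r.source),
                _fmt(r.sink),
                "-".join(_fmt(n) for n in r.consensus_nodes) or "NA",
                "-".join(_fmt(n) for n in r.stable_path) if r.stable_path else "NA",
            )
            for r in results
        ],
    )
    if len(results) >= 2:
        common = sorted(psn.common_path_residues(results))
        summary["common_path_residues"] = "-".join(_fmt(n) for n in common) or "NA"
    summary["i_min"] = f"{params.i_min:.6f}"
    summary["stable_edges"] = len(ens_net.stable_edges)


def _interface(config: RunConfig, out: Path, summary: dict) -> None:
    ensemble = _resolve_ensemble(config, out, "interface")
    chain_a = config.get_str("interface", "chain_a")
    chain_b = config.get_str("interface", "chain_b")
    params = _energy_params(config)
    stride = config.get_int("interface", "stride")
    residues = iface.interface_residues(
        ensemble[0], chain_a, chain_b, params.interface_cutoff
    )
    _write_tsv(
        out / "interface.tsv",
        config.sha256,
        ("residue",),
        [(r,) for r in residues],
    )
    records = iface.hbond_occupancy(ensemble, params.hbond)
    _write_tsv(
        out / "hbonds.tsv",
        config.sha256,
        ("donor_residue", "acceptor_residue", "occupancy", "stable"),
        [
            (r.donor_residue, r.acceptor_residue, r.occupancy, int(r.stable))
            for r in records
        ],
    )
    series = iface.energy_time_series(ensemble, chain_a, chain_b, params, stride)
    _write_tsv(
        out / "energies.tsv",
        config.sha256,
        (
            "frame",
            "hbond_energy",
            "electrostatic_energy",
            "vdw_energy",
            "total_stabilizing",
            "n_interface_residues",
            "normalized_per_residue",
        ),
        [
            (
                frame,
                e.hbond_energy,
                e.electrostatic_energy,
                e.vdw_energy,
                e.total_stabilizing,
                e.n_interface_residues,
                e.normalized_per_residue,
            )
            for frame, e in series
        ],
    )
    spots = iface.hotspots(ensemble[0], chain_a, chain_b, params)
    _write_tsv(out / "hotspots.tsv", config.sha256, ("residue",), [(r,) for r in spots])
    summary["n_interface_residues"] = len(residues)
    summary["stable_hbonds"] = sum(1 for r in records if r.stable)
    summary["n_hotspots"] = len(spots)


def _metrics(config: RunConfig, out: Path, summary: dict) -> None:
    ensemble = _resolve_ensemble(config, out, "metrics")
    ref_path = config.get("inputs", "reference")
    reference = read_pdb(ref_path)[0] if ref_path else ensemble[0]
    selection = config.get_str("metrics", "selection")
    rmsd = met.rmsd_series(ensemble, reference, selection)
    rg = met.rg_series(ensemble)
    _write_tsv(
        out / "metrics_frames.tsv",
        config.sha256,
        ("frame", "rmsd", "rg"),
        [(k, float(rmsd.values[k]), float(rg.values[k])) for k in range(len(ensemble))],
    )
    if len(ensemble) >= 2:
        fluct = met.rmsf(ensemble, window=config.get_float("metrics", "rmsf_window"))
        _write_tsv(
            out / "rmsf.tsv",
            config.sha256,
            ("residue", "rmsf"),
            [(k, float(v)) for k, v in zip(fluct.labels, fluct.values)],
        )
    summary["mean_rmsd"] = f"{float(rmsd.values.mean()):.6f}"
    summary["mean_rg"] = f"{float(rg.values.mean()):.6f}"


_STAGES = {
    "simulate": None,  # handled separately (no summary writes)
    "coevolve": _coevolve,
    "psn": _psn,
    "interface": _interface,
    "metrics": _metrics,
}


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute the configured stages, writing TSV reports into ``out_dir``.

    Returns the summary dictionary (also written to summary.tsv).  Identical
    config and seed produce byte-identical outputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {}
    for stage in config.stages():
        if stage not in _STAGES:
            raise ConfigError(f"unknown stage {stage!r}")
        try:
            if stage == "simulate":
                _simulate(config, out)
            else:
                _STAGES[stage](config, out, summary)
        except (PipelineError, ConfigError):
            raise
        except Exception as exc:
            raise PipelineError(f"{stage} stage failed: {exc}") from exc
    _write_tsv(
        out / "summary.tsv",
        config.sha256,
        ("key", "value"),
        sorted((k, v) for k, v in summary.items()),
    )
    return summary
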