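"""Plain-TSV output, run manifests and reproducible experiment driving.

All tables are tab-separated with ``#``-prefixed ``key<TAB>value`` metadata
header lines, loadable with any standard table reader (skip ``#`` lines).
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import pandas as pd

from . import __version__
from .architecture import GenomeArchitecture, build_architecture
from .engine import GenerationRecord, Trajectory, run_replicates
from .params import SimulationParameters
from .analytics import annotate_phases, classify_outcome

MB = 1_000_000
KB = 1_000


def architecture_config(arch: GenomeArchitecture) -> dict:
    """JSON-serializable echo of an architecture (Mb / cM-per-Mb / kb units)."""
    return {
        "genome_mb": [c.length_bp / MB for c in arch.chromosomes],
        "rr_cm_mb": [c.recomb_rate for c in arch.chromosomes],
        "cluster_kb": [c.cluster_len_bp / KB for c in arch.chromosomes],
        "ref_kb": [c.ref_len_bp / KB for c in arch.chromosomes],
    }


def architecture_from_config(cfg: dict) -> GenomeArchitecture:
    return build_architecture(
        cfg["genome_mb"], cfg["rr_cm_mb"], cfg["cluster_kb"], cfg.get("ref_kb") or None
    )


def _header_lines(params: SimulationParameters, arch: GenomeArchitecture, replicate) -> str:
    meta = {"trapsim_version": __version__, "replicate": replicate}
    meta.update(params.to_dict())
    meta.update({k: ",".join(map(str, v)) for k, v in architecture_config(arch).items()})
    return "".join(f"# {k}\t{v}\n" for k, v in meta.items())


def write_trajectory(
    traj: Trajectory, arch: GenomeArchitecture, path
) -> None:
    """One row per recorded generation plus a ``#`` parameter-echo header."""
    df = traj.to_frame()
    df.insert(0, "replicate", traj.replicate)
    df["status"] = traj.status
    with open(path, "w") as fh:
        fh.write(_header_lines(traj.params, arch, traj.replicate))
        df.to_csv(fh, sep="\t", index=False)


def read_trajectory(path) -> tuple[pd.DataFrame, dict]:
    """Return (records frame, metadata dict) from a trajectory TSV."""
    meta: dict[str, str] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if not line.startswith("#"):
                fh.seek(pos)
                break
            key, _, value = line[1:].strip().partition("\t")
            meta[key] = value
            pos = fh.tell()
        df = pd.read_csv(fh, sep="\t")
    return df, meta


def trajectory_from_file(path) -> Trajectory:
    """Rebuild a :class:`Trajectory` (records + params) from a TSV file."""
    df, meta = read_trajectory(path)
    params = SimulationParameters(
        u=float(meta.get("u", 0.1)),
        v=float(meta.get("v", 0.0)),
        x=float(meta.get("x", 0.0)),
        t=float(meta.get("t", 1.0)),
        model=meta.get("model", "linear"),
        N=int(meta.get("N", 1000)),
        n_seed=int(meta.get("n_seed", 10)),
        generations=int(meta.get("generations", 5000)),
        replicates=int(meta.get("replicates", 1)),
        seed=int(meta.get("seed", 0)),
    )
    records = [
        GenerationRecord(**{c: row[c] for c in GenerationRecord.COLUMNS})
        for _, row in df.iterrows()
    ]
    status = str(df["status"].iloc[-1]) if "status" in df else "completed"
    replicate = int(df["replicate"].iloc[0]) if "replicate" in df else 0
    return Trajectory(params=params, records=records, status=status, replicate=replicate)


def file_checksum(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(
    path,
    params: SimulationParameters,
    arch: GenomeArchitecture,
    replicate_seeds: list[tuple[int, int]],
) -> None:
    manifest = {
        "trapsim_version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "parameters": params.to_dict(),
        "architecture": architecture_config(arch),
        "master_seed": params.seed,
        "replicate_seeds": [
            {"replicate": r, "spawn_key": k} for r, k in replicate_seeds
        ],
    }
    Path(path).write_text(json.dumps(manifest, indent=2) + "\n")


def run_experiment(
    config: dict,
    out_dir,
    *,
    established_only: bool = False,
    verbose: bool = False,
) -> Path:
    """Run a full experiment from a config dict and write all outputs.

    Config keys: the :class:`SimulationParameters` fields plus the
    architecture keys ``genome_mb``, ``rr_cm_mb``, ``cluster_kb``, ``ref_kb``
    (or ``scenario: <name>``). Writes ``manifest.json``, one trajectory TSV
    per replicate and a phase/outcome ``summary.tsv``.
    """
    config = dict(config)
    if "scenario" in config:
        from .architecture import predefined_scenarios

        arch, base = predefined_scenarios(config.pop("scenario"))
        defaults = base.to_dict()
    else:
        arch = architecture_from_config(config)
        defaults = SimulationParameters().to_dict()
        for k in ("genome_mb", "rr_cm_mb", "cluster_kb", "ref_kb"):
            config.pop(k, None)
    defaults.update({k: v for k, v in config.items() if k in defaults})
    params = SimulationParameters(**defaults)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    trajs = run_replicates(arch, params, established_only=established_only)
    write_manifest(
        out / "manifest.json",
        params,
        arch,
        [(t.replicate, t.replicate) for t in trajs],
    )
    rows = []
    for traj in trajs:
        fname = out / f"trajectory_rep{traj.replicate}.tsv"
        write_trajectory(traj, arch, fname)
        ann = annotate_phases(traj)
        oc = classify_outcome(traj)
        row = {
            "replicate": traj.replicate,
            "status": traj.status,
            "outcome": oc.outcome,
            "quadrant": oc.quadrant,
            "shotgun_onset": ann.shotgun_onset,
            "inactive_onset": ann.inactive_onset,
            "final_mean_copies": traj.records[-1].mean_copies,
            "final_mean_cluster": traj.records[-1].mean_cluster,
        }
        rows.append(row)
        if verbose:
            print(f"replicate {traj.replicate}: {traj.status}, {oc.outcome}")
    summary = pd.DataFrame(rows)
    with open(out / "summary.tsv", "w") as fh:
        fh.write(_header_lines(params, arch, "all"))
        summary.to_csv(fh, sep="\t", index=False)
    return out
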