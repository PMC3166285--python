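"""End-to-end orchestration: run the survey stages from a config file.

The pipeline executes, in dependency order: classification of sequences into
RING types, conservation scoring of the alignment, ensemble superposition
with SCR detection, hydrophobic-core analysis, interface contact mapping,
and RBBH orthology with architecture diffing.  Each stage's output is written
as TSV/JSON artifacts; the consolidated survey report mirrors the per-type
summary-table layout (counts, ortholog fractions, SCR table, interface
counts).  Stage outputs are cached by a content hash of their inputs and
parameters, so partial reruns are cheap and reruns are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from ringscan import conservation, interfaces, structure_compare
from ringscan.io_model import (
    read_alignment,
    read_architectures,
    read_hits,
    read_sequences,
    read_structure,
)
from ringscan.orthology_domains import compare_architectures, rbbh
from ringscan.ring_classifier import classify_sequence
from ringscan.structure_compare import SCRParams

log = logging.getLogger("ringscan.pipeline")


@dataclass
class RunConfig:
    """Paths, stage toggles and parameters for one pipeline run."""

    output_dir: str = "ringscan_out"
    seed: int = 0
    # stage inputs (absent path disables the stage unless toggled explicitly)
    sequences_fasta: str | None = None
    msa_fasta: str | None = None
    ensemble_dir: str | None = None
    ensemble_alignment: str | None = None
    complex_pdb: str | None = None
    e3_selection: str | None = None
    e2_selection: str | None = None
    hits_ab: str | None = None
    hits_ba: str | None = None
    architectures_a: str | None = None
    architectures_b: str | None = None
    # stage toggles
    stages: dict = field(default_factory=lambda: {
        "classify": True, "conservation": True, "scr": True,
        "interface": True, "orthology": True, "architecture": True,
    })
    # parameters
    scr_window: int = 3
    scr_threshold: float = 3.0
    scr_min_len: int = 3
    consensus_level: float = 0.8
    conservation_index_min: int = 4
    contact_cutoff: float = 4.0
    close_cutoff: float = 3.5
    region_labels: list = field(default_factory=lambda: [
        "N-loop", "beta", "beta-alpha", "C-loop",
    ])

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        return cfg


def _content_hash(parts: list) -> str:
    h = hashlib.sha256()
    for part in parts:
        if isinstance(part, (str, Path)) and len(str(part)) < 4096:
            try:
                if Path(part).is_file():
                    h.update(Path(part).read_bytes())
            except OSError:
                pass
        h.update(repr(part).encode())
    return h.hexdigest()[:16]


def _cached(outdir: Path, stage: str, key: str, compute):
    cache = outdir / "cache" / f"{stage}-{key}.json"
    if cache.exists():
        log.info("stage %s: cache hit (%s)", stage, key)
        return json.loads(cache.read_text())
    result = compute()
    cache.parent.mkdir(parents=True, exist_ok=True)
    cache.write_text(json.dumps(result, sort_keys=True, indent=1))
    return result


def _round_floats(obj, ndigits=4):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def summarize_types(assignments: list[dict], ortholog_pairs: list[dict]) -> dict:
    """Per-type counts and the fraction of sequences with orthologs."""
    counts: dict[str, int] = {}
    for a in assignments:
        counts[a["type"]] = counts.get(a["type"], 0) + 1
    with_ortholog = {p["id_a"] for p in ortholog_pairs} | {
        p["id_b"] for p in ortholog_pairs
    }
    n = len(assignments)
    n_orth = sum(1 for a in assignments if a["seq_id"] in with_ortholog)
    return {
        "per_type_counts": dict(sorted(counts.items())),
        "n_sequences": n,
        "n_with_orthologs": n_orth,
        "ortholog_percentage": round(100.0 * n_orth / n, 1) if n else 0.0,
    }


def _stage_classify(cfg: RunConfig) -> list[dict]:
    records = read_sequences(cfg.sequences_fasta)
    out = []
    for rec in records:
        a = classify_sequence(rec)
        out.append({
            "seq_id": a.seq_id,
            "type": a.type_label,
            "positions": list(a.ligand_positions),
            "letters": "".join(a.ligand_letters),
            "substitutions": [[p, l] for p, l in a.substitutions],
        })
    return out


def _stage_conservation(cfg: RunConfig, scr_segments) -> dict:
    alignment = read_alignment(cfg.msa_fasta)
    profiles = conservation.profile_alignment(alignment, cfg.consensus_level)
    conserved, ligand = conservation.call_conserved_columns(
        alignment,
        scr_segments=None,
        level_threshold=cfg.consensus_level,
        index_threshold=cfg.conservation_index_min,
    )
    return {
        "columns": [
            {
                "column": p.column,
                "n": p.n_nongap,
                "symbol": p.consensus_symbol,
                "level": round(p.consensus_level, 4),
                "index": p.conservation_index,
            }
            for p in profiles
        ],
        "conserved_columns": [p.column for p in conserved],
    }


def _stage_scr(cfg: RunConfig) -> dict:
    alignment = read_alignment(cfg.ensemble_alignment)
    directory = Path(cfg.ensemble_dir)
    structures = [
        read_structure(p) for p in sorted(directory.glob("*.pdb"))
    ]
    profile = structure_compare.column_rmsd_profile(structures, alignment)
    params = SCRParams(
        window=cfg.scr_window, threshold=cfg.scr_threshold, min_len=cfg.scr_min_len
    )
    segments = structure_compare.detect_scrs(profile, params)
    structure_compare.label_segments_by_plan(segments, cfg.region_labels)
    return {
        "profile": [
            None if g or v != v else round(float(v), 4)
            for v, g in zip(profile.rmsd, profile.has_gap)
        ],
        "segments": [
            {
                "start": s.start_col,
                "end": s.end_col,
                "length": s.length,
                "mean_rmsd": round(s.mean_rmsd, 4),
                "region": s.region_label,
            }
            for s in segments
        ],
    }


def _stage_interface(cfg: RunConfig, scr_result, alignment_path) -> dict:
    structure = read_structure(cfg.complex_pdb)
    e3 = interfaces.Selection.parse(cfg.e3_selection)
    e2 = interfaces.Selection.parse(cfg.e2_selection)
    params = interfaces.ContactParams(
        contact_cutoff=cfg.contact_cutoff, close_cutoff=cfg.close_cutoff
    )
    records = interfaces.extract_contacts(structure, e3, e2, params)
    hbonds = interfaces.detect_backbone_hbonds(structure, e3, e2, cfg.close_cutoff)
    contact_rows = [
        {
            "e3": r.e3_residue.label,
            "e2": r.e2_residue.label,
            "distance": round(r.min_distance, 3),
            "tier": r.tier,
        }
        for r in records
    ]
    return {
        "contacts": contact_rows,
        "n_contact_residues_e3": len({r.e3_residue.label for r in records}),
        "n_close_residues_e3": interfaces.count_close_e3_residues(records),
        "hbonds": [
            {
                "donor": b.donor_residue.label,
                "acceptor": b.acceptor_residue.label,
                "distance": round(b.distance, 3),
            }
            for b in hbonds
        ],
    }


def _stage_orthology(cfg: RunConfig) -> list[dict]:
    pairs = rbbh(read_hits(cfg.hits_ab), read_hits(cfg.hits_ba))
    return [
        {
            "id_a": p.id_a, "id_b": p.id_b,
            "score_ab": p.score_ab, "score_ba": p.score_ba,
        }
        for p in pairs
    ]


def _stage_architecture(cfg: RunConfig, ortholog_pairs: list[dict]) -> list[dict]:
    archs_a = {a.protein_id: a for a in read_architectures(cfg.architectures_a)}
    archs_b = {a.protein_id: a for a in read_architectures(cfg.architectures_b)}
    diffs = []
    for pair in ortholog_pairs:
        a = archs_a.get(pair["id_a"])
        b = archs_b.get(pair["id_b"])
        if a is None or b is None:
            continue
        diff = compare_architectures(a, b)
        diffs.append({
            "id_a": pair["id_a"],
            "id_b": pair["id_b"],
            "relation": diff.relation,
            "inserted": [[n, p] for n, p in diff.inserted],
            "deleted": [[n, p] for n, p in diff.deleted],
        })
    return diffs


def run(config: RunConfig) -> dict:
    """Execute the enabled stages and write the consolidated survey report.

    Stage failures halt their dependents but independent stages still run;
    the report records any failures.  A rerun with identical inputs and
    parameters produces a byte-identical report.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    report: dict = {"parameters": _round_floats({
        k: v for k, v in asdict(config).items() if not isinstance(v, dict)
    }), "stages_run": [], "failures": {}}
    try:
        enabled = {k for k, v in config.stages.items() if v}

        def want(stage: str, *paths) -> bool:
            return stage in enabled and all(p is not None for p in paths)

        assignments: list[dict] = []
        if want("classify", config.sequences_fasta):
            key = _content_hash([config.sequences_fasta, "classify"])
            assignments = _cached(outdir, "classify", key,
                                  lambda: _stage_classify(config))
            report["assignments"] = assignments
            report["stages_run"].append("classify")

        scr_result = None
        if want("scr", config.ensemble_dir, config.ensemble_alignment):
            try:
                key = _content_hash([
                    config.ensemble_alignment, config.scr_window,
                    config.scr_threshold, config.scr_min_len,
                    sorted(str(p) for p in Path(config.ensemble_dir).glob("*.pdb")),
                ])
                scr_result = _cached(outdir, "scr", key, lambda: _stage_scr(config))
                report["scr"] = {"segments": scr_result["segments"]}
                report["stages_run"].append("scr")
            except Exception as exc:  # noqa: BLE001 - reported, dependents halted
                log.error("scr stage failed: %s", exc)
                report["failures"]["scr"] = str(exc)

        if want("conservation", config.msa_fasta):
            key = _content_hash([
                config.msa_fasta, config.consensus_level,
                config.conservation_index_min,
            ])
            cons = _cached(outdir, "conservation", key,
                           lambda: _stage_conservation(config, None))
            report["conservation"] = {
                "conserved_columns": cons["conserved_columns"],
                "n_columns": len(cons["columns"]),
            }
            (outdir / "columns.tsv").write_text(
                "column\tn\tsymbol\tlevel\tindex\n" + "".join(
                    f"{c['column']}\t{c['n']}\t{c['symbol'] or '.'}"
                    f"\t{c['level']}\t{c['index']}\n"
                    for c in cons["columns"]
                )
            )
            report["stages_run"].append("conservation")

        if want("interface", config.complex_pdb, config.e3_selection,
                config.e2_selection):
            key = _content_hash([
                config.complex_pdb, config.e3_selection, config.e2_selection,
                config.contact_cutoff, config.close_cutoff,
            ])
            iface = _cached(outdir, "interface", key,
                            lambda: _stage_interface(config, scr_result, None))
            report["interface"] = iface
            report["stages_run"].append("interface")

        ortholog_pairs: list[dict] = []
        if want("orthology", config.hits_ab, config.hits_ba):
            key = _content_hash([config.hits_ab, config.hits_ba])
            ortholog_pairs = _cached(outdir, "orthology", key,
                                     lambda: _stage_orthology(config))
            report["orthologs"] = {
                "n_pairs": len(ortholog_pairs),
                "pairs": ortholog_pairs,
            }
            report["stages_run"].append("orthology")

        if want("architecture", config.architectures_a, config.architectures_b):
            if "orthology" in report.get("failures", {}):
                report["failures"]["architecture"] = "dependent on failed orthology"
            else:
                key = _content_hash([
                    config.architectures_a, config.architectures_b,
                    json.dumps(ortholog_pairs, sort_keys=True),
                ])
                diffs = _cached(
                    outdir, "architecture", key,
                    lambda: _stage_architecture(config, ortholog_pairs),
                )
                report["architecture_diffs"] = diffs
                report["stages_run"].append("architecture")

        if assignments:
            report["type_summary"] = summarize_types(assignments, ortholog_pairs)

        report_text = json.dumps(_round_floats(report), sort_keys=True, indent=1)
        (outdir / "report.json").write_text(report_text + "\n")
        return report
    finally:
        log.removeHandler(handler)
        handler.close()
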