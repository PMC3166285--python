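"""Materialize a complete synthetic demo input set plus a pipeline config.

The bundled demo emulates the survey's study conditions at desk scale:
planted RING sequences across the named types, a conserved-column alignment,
a ten-member superposed ensemble with four low-noise regions (lengths
9/7/13/6 at 0.3 A among 4.0 A spacers), a two-chain complex with planted
contact pairs, reciprocal hit tables with planted orthologs, and a pair of
domain-architecture tables containing one CARD-insertion event.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from ringscan import synthetic_data as synth
from ringscan.io_model import write_alignment, write_fasta, write_hits, write_structure
from ringscan.pipeline import RunConfig

DEMO_TYPE_COUNTS = (
    ("C3HC4", 5), ("C3H2C3", 3), ("C3HC3D", 2), ("C4HC3", 2),
    ("C3HGC3", 2), ("C4C4", 2),
)


def write_demo_inputs(directory: str | Path, seed: int = 20110902) -> Path:
    """Write every demo input under ``directory``; returns the config path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    # sequences with planted ligand patterns
    records, seq_truth = synth.gen_ring_sequences(
        synth.RingSequenceSpec(seed=seed, counts=DEMO_TYPE_COUNTS)
    )
    write_fasta(records, directory / "sequences.fasta")
    (directory / "sequences.truth.json").write_text(json.dumps(
        [
            {"seq_id": t.seq_id, "type": t.type_label,
             "positions": list(t.positions)}
            for t in seq_truth
        ], indent=1))

    # alignment with planted conserved columns (4 hydrophobic + 2 polar)
    msa_spec = synth.MsaSpec(
        seed=seed + 1,
        n_rows=30,
        n_cols=46,
        planted=((4, "h", 0.9), (18, "h", 0.9), (22, "h", 0.9),
                 (25, "p", 0.9), (40, "h", 0.9), (43, "p", 0.9)),
    )
    msa, msa_truth = synth.gen_msa(msa_spec)
    write_alignment(msa, directory / "msa.fasta")
    (directory / "msa.truth.json").write_text(json.dumps(
        [{"column": t.column, "symbol": t.symbol, "level": t.level}
         for t in msa_truth], indent=1))

    # superposed ensemble with four planted low-noise regions
    ens_dir = directory / "ensemble"
    ens_dir.mkdir(exist_ok=True)
    structures, alignment, ens_truth = synth.gen_ensemble(
        synth.EnsembleSpec(seed=seed + 2)
    )
    for st in structures:
        write_structure(st, ens_dir / f"{st.id}.pdb")
    write_alignment(alignment, directory / "ensemble.aln.fasta")
    (directory / "ensemble.truth.json").write_text(json.dumps(
        {"regions": [list(r) for r in ens_truth.regions]}, indent=1))

    # two-chain complex with planted cross-chain pairs
    complex_spec = synth.ComplexSpec(
        seed=seed + 3,
        pair_plan=((2.9, "CA", "CA"), (3.1, "CA", "CA"), (3.3, "CA", "CA"),
                   (3.45, "CA", "CA"), (3.5, "CA", "CA"), (3.7, "CA", "CA"),
                   (3.9, "CA", "CA"), (4.0, "CA", "CA"), (4.2, "CA", "CA"),
                   (5.5, "CA", "CA")),
    )
    complex_structure, complex_truth = synth.gen_complex(complex_spec)
    write_structure(complex_structure, directory / "complex.pdb")
    (directory / "complex.truth.json").write_text(json.dumps(
        [{"e3": t.e3_seq_num, "e2": t.e2_seq_num,
          "distance": round(t.distance, 3), "tier": t.tier}
         for t in complex_truth], indent=1))

    # reciprocal hit tables with planted orthologs: one per classified
    # sequence except two, so the type summary has a known ortholog fraction
    n_seq = sum(c for _, c in DEMO_TYPE_COUNTS)
    hits_spec = synth.HitsSpec(
        seed=seed + 4, size_a=n_seq, size_b=n_seq,
        n_orthologs=n_seq - 2, noise_rate=0.10, n_tie_cases=2,
    )
    hits_ab, hits_ba, hit_truth = synth.gen_hits(hits_spec)
    # rename A-side ids to the demo sequence ids so summaries join up
    id_map = {f"A{i:04d}": rec.id for i, rec in enumerate(records)}
    hits_ab = [
        type(h)(id_map.get(h.query_id, h.query_id), h.subject_id,
                h.pct_identity, h.bit_score, h.e_value)
        for h in hits_ab
    ]
    hits_ba = [
        type(h)(h.query_id, id_map.get(h.subject_id, h.subject_id),
                h.pct_identity, h.bit_score, h.e_value)
        for h in hits_ba
    ]
    hit_truth = [(id_map[a], b) for a, b in hit_truth]
    write_hits(hits_ab, directory / "hits_ab.tsv")
    write_hits(hits_ba, directory / "hits_ba.tsv")
    (directory / "hits.truth.json").write_text(json.dumps(
        [[a, b] for a, b in hit_truth], indent=1))

    # architecture tables: identical except one CARD insertion on the B side
    arch_rows_a = ["protein_id\tdomain\tstart\tend"]
    arch_rows_b = ["protein_id\tdomain\tstart\tend"]
    for k, (a, b) in enumerate(hit_truth):
        domains = [("BIR", 10, 80), ("BIR", 100, 170), ("BIR", 190, 260),
                   ("RING", 300, 345)]
        arch_rows_a.extend(f"{a}\t{n}\t{s}\t{e}" for n, s, e in domains)
        if k == 0:  # the planted expansion event
            domains_b = domains[:3] + [("CARD", 270, 295)] + domains[3:]
        else:
            domains_b = domains
        arch_rows_b.extend(f"{b}\t{n}\t{s}\t{e}" for n, s, e in domains_b)
    (directory / "arch_a.tsv").write_text("\n".join(arch_rows_a) + "\n")
    (directory / "arch_b.tsv").write_text("\n".join(arch_rows_b) + "\n")

    config = RunConfig(
        output_dir=str(directory / "out"),
        seed=seed,
        sequences_fasta=str(directory / "sequences.fasta"),
        msa_fasta=str(directory / "msa.fasta"),
        ensemble_dir=str(ens_dir),
        ensemble_alignment=str(directory / "ensemble.aln.fasta"),
        complex_pdb=str(directory / "complex.pdb"),
        e3_selection="E",
        e2_selection="F",
        hits_ab=str(directory / "hits_ab.tsv"),
        hits_ba=str(directory / "hits_ba.tsv"),
        architectures_a=str(directory / "arch_a.tsv"),
        architectures_b=str(directory / "arch_b.tsv"),
    )
    config_path = directory / "config.yaml"
    payload = {k: v for k, v in config.__dict__.items()}
    config_path.write_text(yaml.safe_dump(payload, sort_keys=True))
    return config_path
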