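"""End-to-end orchestration: config, conservation runs, structure runs,
dataset summaries.

Every numeric constant of the analysis lives in :class:`PipelineConfig`.
All outputs are tab-separated tables written deterministically (fixed float
format, fixed row order), so identical inputs + config yield byte-identical
files.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import conservation, stats, structure_analysis as sa
from .disorder import PairwiseEnergyPredictor, predict_disorder, disorder_fraction
from .errors import InputError
from .io_formats import read_alignment, read_fasta, read_structure

log = logging.getLogger("discons")

FLOAT_FORMAT = "%.6g"


@dataclass
class PipelineConfig:
    """All thresholds of the analysis in one place (defaults as published)."""

    disorder_threshold: float = 0.5
    contact_distance: float = 5.0        # A
    min_atom_pairs: int = 5
    min_interacting_residues: int = 5
    gap_filter: float = 0.30
    nussinov_threshold: float = 80.0     # A^2 per residue
    identity_threshold: float = 0.9
    background: str = "blosum62"
    scs_window: int = 3
    sasa_points: int = 960
    seed: int = 0

    def __post_init__(self):
        for name in ("disorder_threshold", "contact_distance", "min_atom_pairs",
                     "min_interacting_residues", "gap_filter", "nussinov_threshold",
                     "identity_threshold"):
            if getattr(self, name) <= 0:
                raise InputError(f"config value {name} must be positive")

    def save(self, path) -> None:
        lines = [f"{k} = {v}" for k, v in asdict(self).items()]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        """Read a flat ``key = value`` config document."""
        kwargs = {}
        types = {f.name: f.type for f in fields(cls)}
        casts = {"float": float, "int": int, "str": str}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise InputError(f"{path}:{lineno}: expected 'key = value'")
            key, _, value = (t.strip() for t in line.partition("="))
            if key not in types:
                raise InputError(f"{path}:{lineno}: unknown config key {key!r}")
            kwargs[key] = casts[types[key]](value.strip("'\""))
        return cls(**kwargs)


def _stage(name: str, start: float, **counts) -> None:
    extras = " ".join(f"{k}={v}" for k, v in counts.items())
    log.info("stage=%s elapsed=%.2fs %s", name, time.monotonic() - start, extras)


def _file_hash(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def annotations_frame(annotations) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "column_index": [a.column_index for a in annotations],
            "scs": [a.scs for a in annotations],
            "dcs": [a.dcs for a in annotations],
            "gap_fraction": [a.gap_fraction for a in annotations],
            "category": [a.category for a in annotations],
            "scs_binned": [a.scs_binned for a in annotations],
            "dcs_binned": [a.dcs_binned for a in annotations],
        }
    )


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def run_conservation_pipeline(msa_path, config: PipelineConfig | None = None,
                              predictor=None, profiles=None,
                              out_path=None) -> pd.DataFrame:
    """MSA -> per-column SCS/DCS/category table.

    Disorder profiles are computed on the ungapped rows with ``predictor``
    (default: the shipped pairwise-energy predictor) unless precomputed
    ``profiles`` are supplied.
    """
    config = config or PipelineConfig()
    start = time.monotonic()
    msa = read_alignment(msa_path)
    log.info("input=%s sha256=%s rows=%d cols=%d", msa_path, _file_hash(msa_path),
             msa.n_rows, msa.n_cols)
    if profiles is None:
        predictor = predictor or PairwiseEnergyPredictor()
        profiles = [
            predict_disorder(msa.ungapped(i), predictor, sequence_id=msa.ids[i])
            for i in range(msa.n_rows)
        ]
    annotations = conservation.annotate_msa(
        msa, profiles, background=config.background, window=config.scs_window
    )
    table = annotations_frame(annotations)
    _stage("conservation", start, columns=len(table))
    if out_path is not None:
        write_table(table, out_path)
    return table


def _chain_metrics(structure, chain, config: PipelineConfig, predictor) -> dict:
    nucleic = structure.nucleic_chains()
    pair_counts = np.zeros(len(chain), dtype=int)
    for nc in nucleic:
        result = sa.find_interface_residues(structure, chain.chain_id, nc.chain_id,
                                            cutoff=config.contact_distance)
        pair_counts += result.atom_pair_count
    interface = set(np.nonzero(pair_counts >= config.min_atom_pairs)[0].tolist())
    areas = sa.compute_surface_areas(structure, chain.chain_id, n_points=config.sasa_points)
    call = sa.classify_flexibility(areas, threshold=config.nussinov_threshold)
    partners = sa.count_partners(structure, chain.chain_id,
                                 cutoff=config.contact_distance,
                                 min_residues=config.min_interacting_residues)
    profile = predict_disorder(chain.sequence(), predictor, sequence_id=chain.chain_id)
    labels = sa.assign_secondary_structure(structure, chain.chain_id)
    helix, strand, regular = sa.disordered_region_ss_fractions(labels, profile)
    return {
        "chain_id": chain.chain_id,
        "n_residues": len(chain),
        "n_interface_residues": len(interface) if nucleic else np.nan,
        "interface_fraction": len(interface) / len(chain) if nucleic else np.nan,
        "sasa_chain": areas.sasa_chain,
        "interface_area": areas.interface_area,
        "asa_per_residue": areas.asa_per_residue,
        "interface_per_residue": areas.interface_per_residue,
        "flexibility_side": call.side,
        "partner_count": partners,
        "disorder_fraction": disorder_fraction(profile),
        "helix_fraction_disordered": helix,
        "strand_fraction_disordered": strand,
        "regular_fraction_disordered": regular,
    }


def run_structure_pipeline(structure_path, config: PipelineConfig | None = None,
                           predictor=None, out_path=None) -> pd.DataFrame:
    """Structure file -> one row of interface/area/partner metrics per protein chain."""
    config = config or PipelineConfig()
    predictor = predictor or PairwiseEnergyPredictor()
    start = time.monotonic()
    structure = read_structure(structure_path)
    proteins = structure.protein_chains()
    if not proteins:
        raise InputError(f"{structure_path}: no protein chain found")
    rows = [_chain_metrics(structure, chain, config, predictor) for chain in proteins]
    table = pd.DataFrame(rows)
    _stage("structure", start, chains=len(table))
    if out_path is not None:
        write_table(table, out_path)
    return table


def run_dataset_summary(sequence_dir=None, structure_dir=None, energies_tsv=None,
                        config: PipelineConfig | None = None, predictor=None,
                        out_dir=None) -> dict[str, pd.DataFrame]:
    """Dataset-level tables: grouped disorder fractions, interface composition
    enrichment, and the correlation table (disorder vs interface size, partner
    count vs interface/length/disorder)."""
    config = config or PipelineConfig()
    predictor = predictor or PairwiseEnergyPredictor()
    tables: dict[str, pd.DataFrame] = {}
    if sequence_dir is None and structure_dir is None:
        raise InputError("dataset summary needs a sequence and/or structure directory")

    if sequence_dir is not None:
        start = time.monotonic()
        paths = sorted(Path(sequence_dir).glob("*.fasta"))
        if not paths:
            raise InputError(f"no .fasta files in {sequence_dir}")
        records = [r for p in paths for r in read_fasta(p)]
        profiles = [predict_disorder(r.sequence, predictor, sequence_id=r.id)
                    for r in records]
        for group_by in ("binding_class", "taxon_group"):
            if any(getattr(r, group_by) for r in records):
                tables[f"disorder_by_{group_by}"] = stats.disorder_fraction_summary(
                    records, profiles, group_by=group_by
                )
        _stage("sequences", start, records=len(records))

    if structure_dir is not None:
        start = time.monotonic()
        paths = sorted(
            p for p in Path(structure_dir).iterdir()
            if p.suffix.lower() in (".pdb", ".cif", ".ent")
        )
        if not paths:
            raise InputError(f"no structure files in {structure_dir}")
        chain_rows, iface_counts, all_counts = [], {}, {}
        for path in paths:
            table = run_structure_pipeline(path, config, predictor=predictor)
            table.insert(0, "structure", path.stem)
            chain_rows.append(table)
            structure = read_structure(path)
            for chain in structure.protein_chains():
                seq = chain.sequence()
                nucleic = structure.nucleic_chains()
                pair_counts = np.zeros(len(chain), dtype=int)
                for nc in nucleic:
                    pair_counts += sa.find_interface_residues(
                        structure, chain.chain_id, nc.chain_id,
                        cutoff=config.contact_distance,
                    ).atom_pair_count
                for i, aa in enumerate(seq):
                    all_counts[aa] = all_counts.get(aa, 0) + 1
                    if pair_counts[i] >= config.min_atom_pairs:
                        iface_counts[aa] = iface_counts.get(aa, 0) + 1
        chains = pd.concat(chain_rows, ignore_index=True)
        tables["chains"] = chains
        if iface_counts:
            tables["enrichment_interface"] = stats.composition_enrichment(
                iface_counts, all_counts
            ).rename_axis("amino_acid").reset_index()
        corr_rows = []
        usable = chains.dropna(subset=["interface_per_residue"])
        if len(usable) >= 3:
            corr_rows.append(("disorder_fraction", "interface_per_residue", "pearson",
                              stats.correlate(usable.disorder_fraction,
                                              usable.interface_per_residue, "pearson")))
            for feature, method in (("interface_area", "pearson"),
                                    ("n_residues", "kendall"),
                                    ("disorder_fraction", "kendall")):
                corr_rows.append(("partner_count", feature, method,
                                  stats.correlate(usable.partner_count,
                                                  usable[feature], method)))
        tables["correlations"] = pd.DataFrame(
            corr_rows, columns=["x", "y", "method", "coefficient"]
        )
        _stage("structures", start, files=len(paths), chains=len(chains))

    if energies_tsv is not None:
        start = time.monotonic()
        energies = pd.read_csv(energies_tsv, sep="\t")
        required = {"binding_class", "energy"}
        if not required.issubset(energies.columns):
            raise InputError(f"{energies_tsv}: needs columns {sorted(required)}")
        comp_rows = []
        classes = sorted(energies.binding_class.unique())
        for i, a in enumerate(classes):
            for b in classes[i + 1:]:
                comp = stats.compare_groups({
                    a: energies.loc[energies.binding_class == a, "energy"],
                    b: energies.loc[energies.binding_class == b, "energy"],
                }, test="welch_t")
                comp_rows.append({
                    "group_a": a, "group_b": b, "n_a": comp.n[0], "n_b": comp.n[1],
                    "mean_a": comp.means[0], "mean_b": comp.means[1],
                    "statistic": comp.statistic, "p_value": comp.p_value,
                })
        tables["energy_comparison"] = pd.DataFrame(comp_rows)
        _stage("energies", start, comparisons=len(comp_rows))
    else:
        log.info("stage=energies skipped (no energies_tsv supplied)")

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, table in tables.items():
            write_table(table, out_dir / f"{name}.tsv")
    return tables
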