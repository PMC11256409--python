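"""Seeded synthetic virome studies.

Emulates every upstream tool output the analysis pipeline consumes — viral
candidate genomes, per-contig detector feature tables, paired VLP/bulk
per-base depth vectors, classifier confirmation counts, protein/spacer/
genome hit tables, a sample sheet — together with per-vOTU ground truth,
for parameter-recovery and calibration experiments.

The statistical model: each subject carries one latent vOTU abundance
vector (shared by that subject's VLP and bulk samples), drawn log-normally
around per-vOTU means; planted disease-associated vOTUs are multiplied by
a configured fold change in the favored group; VLP samples additionally
apply family-specific capture-bias factors. Compositions are then closed
per sample, and read depth is Poisson around abundance x target depth.
All randomness fans out from one seed via stable hashing of entity ids,
so regeneration is byte-identical and insertion-order independent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._rng import child_rng
from .annot import kingdom_of

__all__ = ["SimConfig", "SyntheticStudy", "generate_cohort", "generate_depth_vector"]

_PROK_FAMILIES = [
    "Siphoviridae",
    "Myoviridae",
    "Microviridae",
    "Podoviridae",
    "crAss-like",
    "Quimbyviridae",
]
_EUK_FAMILIES = ["Anelloviridae", "Adenoviridae", "Genomoviridae"]
_HOST_POOL = [
    "Escherichia",
    "Klebsiella",
    "Enterococcus_B",
    "Streptococcus",
    "Veillonella",
    "Prevotella",
    "Ruminococcus_E",
    "Bifidobacterium",
    "Blautia",
    "Faecalibacterium",
]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic cohort.

    Defaults encode the planted-signal recovery conditions: 30 cases and
    30 controls (each subject contributing one VLP and one bulk sample),
    50 vOTUs of which 10 are case-enriched and 10 control-enriched at
    fourfold, ~10 reads/bp average depth, and VLP capture bias factors
    mirroring the strongest family-level modality shifts seen in real
    paired viromes (Microviridae strongly over-captured by VLP
    enrichment, Myoviridae under-captured).
    """

    n_case: int = 30
    n_control: int = 30
    n_votus: int = 50
    n_planted_case_enriched: int = 10
    n_planted_control_enriched: int = 10
    effect_fold: float = 4.0
    genome_length_range: tuple[int, int] = (2500, 5000)
    mean_depth: float = 10.0
    vlp_bias_families: dict[str, float] = field(
        default_factory=lambda: {"Microviridae": 10.0, "Myoviridae": 0.23}
    )
    dropout_rate: float = 0.05
    seed: int = 0
    # secondary knobs (kept stable across experiments)
    occupancy: float = 0.9
    subject_sigma: float = 1.0
    cohort_id: str = "study"
    n_decoys: int = 20
    n_duplicates: int = 5
    n_external: int = 5
    n_functions: int = 30
    confirm_rate: float = 20.0

    def validate(self) -> None:
        planted = self.n_planted_case_enriched + self.n_planted_control_enriched
        if planted > self.n_votus:
            raise ValueError(
                "invalid config: n_planted_case_enriched + n_planted_control_enriched "
                f"({planted}) exceeds n_votus ({self.n_votus})"
            )
        if self.effect_fold < 1:
            raise ValueError("invalid config: effect_fold must be >= 1")
        for name in ("dropout_rate", "occupancy"):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"invalid config: {name} must lie in [0, 1]")
        lo, hi = self.genome_length_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid config: bad genome_length_range")
        if min(self.n_case, self.n_control, self.n_votus) < 1:
            raise ValueError("invalid config: counts must be positive")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimConfig":
        data = json.loads(Path(path).read_text())
        if "genome_length_range" in data:
            data["genome_length_range"] = tuple(data["genome_length_range"])
        cfg = cls(**data)
        cfg.validate()
        return cfg


@dataclass
class SyntheticStudy:
    """One generated cohort plus its ground truth."""

    config: SimConfig
    genomes: dict[str, str]
    contig_features: pd.DataFrame
    alignments: pd.DataFrame
    source: dict[str, str]
    abundance: pd.DataFrame  # samples x vOTUs closed compositions (latent)
    depth_store: dict[tuple[str, str], np.ndarray]
    depth_matrix: pd.DataFrame  # samples x vOTUs scalar depths (fast path)
    confirm_counts: pd.DataFrame  # sample, votu, count (long form)
    protein_hits: pd.DataFrame
    spacer_hits: pd.DataFrame
    genome_aln_hits: pd.DataFrame
    function_presence: pd.DataFrame  # functions x vOTUs booleans
    sample_sheet: pd.DataFrame
    truth: pd.DataFrame

    @property
    def votus(self) -> list[str]:
        return list(self.truth["votu_id"])

    def samples(self, modality: str | None = None) -> list[str]:
        sheet = self.sample_sheet
        if modality is not None:
            sheet = sheet[sheet["modality"] == modality]
        return list(sheet["sample_id"])

    def confirm_map(self) -> dict[tuple[str, str], int]:
        return {
            (r.sample_id, r.votu_id): int(r.count)
            for r in self.confirm_counts.itertuples(index=False)
        }

    def profiles(self) -> dict[str, pd.DataFrame]:
        """Per-modality relative-abundance profiles via the abundance model.

        Uses per-base depth vectors (trimmed-depth pipeline) when they were
        simulated, else the scalar depth matrix; either way confirmation
        zeroing and per-sample closure are applied.
        """
        from . import profiler

        confirm = self.confirm_map()
        out = {}
        for modality in ("VLP", "bulk"):
            samples = self.samples(modality)
            if self.depth_store:
                prof = profiler.build_profile(
                    self.depth_store, confirm, samples, self.votus
                )
            else:
                import warnings

                rows = []
                for s in samples:
                    depths = {
                        v: float(self.depth_matrix.loc[s, v]) for v in self.votus
                    }
                    counts = {v: confirm.get((s, v), 0) for v in self.votus}
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        rows.append(
                            profiler.relative_abundance(
                                profiler.apply_confirmation(depths, counts)
                            )
                        )
                prof = pd.DataFrame(rows, index=samples, columns=self.votus)
            out[modality] = prof
        return out

    def groups(self) -> pd.Series:
        return self.sample_sheet.set_index("sample_id")["group"]

    def write(self, outdir: str | Path) -> list[Path]:
        """Write every table of the study as TSV/FASTA under ``outdir``."""
        from . import io as vio

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []

        def _tsv(name: str, frame: pd.DataFrame, index: bool = False) -> None:
            path = outdir / name
            vio.write_tsv(frame, path, index=index)
            written.append(path)

        vio.write_fasta(self.genomes, outdir / "genomes.fasta")
        written.append(outdir / "genomes.fasta")
        _tsv("contig_features.tsv", self.contig_features)
        _tsv("alignments.tsv", self.alignments)
        _tsv(
            "sources.tsv",
            pd.DataFrame(
                sorted(self.source.items()), columns=["sequence_id", "source"]
            ),
        )
        _tsv("confirm_counts.tsv", self.confirm_counts)
        _tsv("hits_protein.tsv", self.protein_hits)
        _tsv("hits_spacer.tsv", self.spacer_hits)
        _tsv("hits_genome.tsv", self.genome_aln_hits)
        _tsv("functions.tsv", self.function_presence, index=True)
        _tsv("samples.tsv", self.sample_sheet)
        _tsv("truth.tsv", self.truth)
        depth_root = outdir / "depth"
        for (sample, votu), vector in sorted(self.depth_store.items()):
            d = depth_root / sample
            d.mkdir(parents=True, exist_ok=True)
            frame = pd.DataFrame(
                {"position": np.arange(1, vector.size + 1), "depth": vector}
            )
            vio.write_tsv(frame, d / f"{votu}.tsv")
        if self.depth_store:
            written.append(depth_root)
        return written


def generate_depth_vector(
    genome_length: int, target_depth: float, seed: int
) -> np.ndarray:
    """Per-base depth vector: i.i.d. Poisson(target_depth) of genome length."""
    if genome_length < 1:
        raise ValueError("genome_length must be at least 1")
    if target_depth < 0:
        raise ValueError("target_depth must be nonnegative")
    rng = np.random.default_rng(seed)
    return rng.poisson(target_depth, size=int(genome_length))


def _assign_families(cfg: SimConfig) -> list[str]:
    rng = child_rng(cfg.seed, "families")
    fams = []
    for _ in range(cfg.n_votus):
        u = rng.random()
        if u < 0.395:
            fams.append(_PROK_FAMILIES[rng.integers(len(_PROK_FAMILIES))])
        elif u < 0.444:
            fams.append(_EUK_FAMILIES[rng.integers(len(_EUK_FAMILIES))])
        else:
            fams.append("unclassified")
    return fams


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def generate_cohort(config: SimConfig, simulate_depth: bool = True) -> SyntheticStudy:
    """Generate one synthetic case-control cohort.

    With ``simulate_depth`` per-base Poisson depth vectors are drawn for
    every detectable (sample, vOTU) pair; otherwise only scalar per-pair
    depths are drawn (orders of magnitude faster, used for calibration
    sweeps over many seeds).
    """
    cfg = config
    cfg.validate()
    seed = cfg.seed

    votus = [f"vOTU{i + 1:04d}" for i in range(cfg.n_votus)]
    families = _assign_families(cfg)
    lengths = {
        v: int(
            child_rng(seed, "length", v).integers(
                cfg.genome_length_range[0], cfg.genome_length_range[1] + 1
            )
        )
        for v in votus
    }

    # planted status
    rng_plant = child_rng(seed, "plant")
    order = list(rng_plant.permutation(cfg.n_votus))
    case_set = {votus[i] for i in order[: cfg.n_planted_case_enriched]}
    control_set = {
        votus[i]
        for i in order[
            cfg.n_planted_case_enriched : cfg.n_planted_case_enriched
            + cfg.n_planted_control_enriched
        ]
    }
    status = {
        v: "case_enriched"
        if v in case_set
        else ("control_enriched" if v in control_set else "null")
        for v in votus
    }

    # hosts for prokaryotic-leaning vOTUs
    hosts = {}
    for v, fam in zip(votus, families):
        rng_h = child_rng(seed, "host", v)
        if kingdom_of(fam) != "eukaryotic" and rng_h.random() < 0.8:
            hosts[v] = _HOST_POOL[rng_h.integers(len(_HOST_POOL))]
        else:
            hosts[v] = ""

    # per-vOTU base abundance means (heavy-tailed)
    rng_base = child_rng(seed, "base")
    base_mean = {v: float(np.exp(rng_base.normal(0.0, 1.0))) for v in votus}
    bias = np.array(
        [cfg.vlp_bias_families.get(fam, 1.0) for fam in families], dtype=float
    )
    base = np.array([base_mean[v] for v in votus])
    fold_mask_case = np.array([v in case_set for v in votus])
    fold_mask_control = np.array([v in control_set for v in votus])

    subjects = [(f"C{i + 1:03d}", "IBD") for i in range(cfg.n_case)] + [
        (f"H{i + 1:03d}", "control") for i in range(cfg.n_control)
    ]

    sample_rows = []
    abundance_rows: dict[str, np.ndarray] = {}
    depth_store: dict[tuple[str, str], np.ndarray] = {}
    depth_scalar: dict[str, np.ndarray] = {}
    confirm_rows = []

    for subj, group in subjects:
        rng_s = child_rng(seed, "subject", cfg.cohort_id, subj)
        present = rng_s.random(cfg.n_votus) < cfg.occupancy
        noise = np.exp(rng_s.normal(0.0, cfg.subject_sigma, size=cfg.n_votus))
        latent = base * noise * present
        if group == "IBD":
            latent = np.where(fold_mask_case, latent * cfg.effect_fold, latent)
        else:
            latent = np.where(fold_mask_control, latent * cfg.effect_fold, latent)

        spurious = (~present) & (rng_s.random(cfg.n_votus) < cfg.dropout_rate)

        for modality in ("VLP", "bulk"):
            sample_id = f"{subj}_{modality.lower()}"
            weights = latent * bias if modality == "VLP" else latent
            total = weights.sum()
            closed = weights / total if total > 0 else weights
            abundance_rows[sample_id] = closed
            sample_rows.append(
                {
                    "sample_id": sample_id,
                    "subject": subj,
                    "group": group,
                    "modality": modality,
                    "cohort": cfg.cohort_id,
                }
            )

            expected = closed * cfg.mean_depth * cfg.n_votus
            expected = np.where(spurious, 0.5, expected)
            rng_m = child_rng(seed, "reads", cfg.cohort_id, sample_id)
            for j, v in enumerate(votus):
                e = expected[j]
                if e <= 0:
                    count = 0
                else:
                    if simulate_depth:
                        vec = generate_depth_vector(
                            lengths[v],
                            e,
                            np.random.SeedSequence(
                                [seed & 0x7FFFFFFF, hash_tokens(cfg.cohort_id, sample_id, v)]
                            ).generate_state(1)[0],
                        )
                        depth_store[(sample_id, v)] = vec
                    if spurious[j]:
                        count = 0  # classifier never confirms spurious depth
                    else:
                        count = 1 + int(rng_m.poisson(e * cfg.confirm_rate))
                confirm_rows.append(
                    {"sample_id": sample_id, "votu_id": v, "count": count}
                )
            if not simulate_depth:
                rng_d = child_rng(seed, "scalar_depth", cfg.cohort_id, sample_id)
                lens = np.array([lengths[v] for v in votus], dtype=float)
                depth_scalar[sample_id] = rng_d.poisson(expected * lens) / lens

    abundance = pd.DataFrame.from_dict(
        abundance_rows, orient="index", columns=votus
    ).loc[[r["sample_id"] for r in sample_rows]]

    genomes = {
        v: _random_sequence(child_rng(seed, "genome", v), lengths[v]) for v in votus
    }
    source = {v: "study" for v in votus}
    contig_rows = [
        _viral_contig_row(cfg, v, lengths[v]) for v in votus
    ] + _decoy_rows(cfg)
    aln_rows = []

    # near-duplicate study contigs exercising the dereplication stage
    rng_dup = child_rng(seed, "dups")
    dup_parents = [votus[i] for i in rng_dup.permutation(cfg.n_votus)[: cfg.n_duplicates]]
    for i, parent in enumerate(dup_parents):
        did = f"dup{i + 1:03d}"
        dlen = int(lengths[parent] * 0.9)
        genomes[did] = genomes[parent][:dlen]
        source[did] = "study"
        aln_rows.append(
            {
                "query_id": did,
                "subject_id": parent,
                "q_start": 1,
                "q_end": dlen,
                "s_start": 1,
                "s_end": dlen,
                "percent_identity": 97.0,
                "query_length": dlen,
                "subject_length": lengths[parent],
            }
        )
    # external-catalog genomes: some redundant with study vOTUs, some isolated
    rng_ext = child_rng(seed, "external")
    for i in range(cfg.n_external):
        eid = f"ext{i + 1:03d}"
        if i < cfg.n_external * 3 // 5:
            parent = votus[int(rng_ext.integers(cfg.n_votus))]
            elen = int(lengths[parent] * 0.85)
            genomes[eid] = genomes[parent][:elen]
            aln_rows.append(
                {
                    "query_id": eid,
                    "subject_id": parent,
                    "q_start": 1,
                    "q_end": elen,
                    "s_start": 1,
                    "s_end": elen,
                    "percent_identity": 96.5,
                    "query_length": elen,
                    "subject_length": lengths[parent],
                }
            )
        else:
            elen = int(rng_ext.integers(*cfg.genome_length_range))
            genomes[eid] = _random_sequence(child_rng(seed, "genome", eid), elen)
        source[eid] = "external"

    alignments = pd.DataFrame(
        aln_rows,
        columns=[
            "query_id",
            "subject_id",
            "q_start",
            "q_end",
            "s_start",
            "s_end",
            "percent_identity",
            "query_length",
            "subject_length",
        ],
    )

    contig_features = pd.DataFrame(contig_rows)
    gene_totals = {
        r["contig_id"]: r["total_gene_count"]
        for r in contig_rows
        if r["contig_id"] in set(votus)
    }
    protein_hits = _protein_hits(cfg, votus, families, gene_totals)
    spacer_rows, aln_host_rows = _host_hits(cfg, votus, hosts)
    function_presence = _function_presence(cfg, votus, status)

    truth = pd.DataFrame(
        {
            "votu_id": votus,
            "status": [status[v] for v in votus],
            "family": families,
            "kingdom": [kingdom_of(f) for f in families],
            "host": [hosts[v] for v in votus],
            "genome_length": [lengths[v] for v in votus],
        }
    )

    return SyntheticStudy(
        config=cfg,
        genomes=genomes,
        contig_features=contig_features,
        alignments=alignments,
        source=source,
        abundance=abundance,
        depth_store=depth_store,
        depth_matrix=pd.DataFrame.from_dict(
            depth_scalar, orient="index", columns=votus
        )
        if depth_scalar
        else pd.DataFrame(columns=votus),
        confirm_counts=pd.DataFrame(confirm_rows),
        protein_hits=protein_hits,
        spacer_hits=pd.DataFrame(
            spacer_rows, columns=["votu_id", "host_genome_id", "bit_score"]
        ),
        genome_aln_hits=pd.DataFrame(
            aln_host_rows,
            columns=["votu_id", "host_genome_id", "percent_identity", "viral_coverage"],
        ),
        function_presence=function_presence,
        sample_sheet=pd.DataFrame(sample_rows),
        truth=truth,
    )


def hash_tokens(*tokens: object) -> int:
    from ._rng import child_seed

    return child_seed(0, *tokens)


def _viral_contig_row(cfg: SimConfig, votu: str, length: int) -> dict:
    rng = child_rng(cfg.seed, "contig", votu)
    viral = 1 + int(rng.poisson(length / 1000 * 1.0))
    host = int(rng.poisson(0.5))
    total = viral + host + int(rng.poisson(1.0))
    return {
        "contig_id": votu,
        "length": length,
        "viral_gene_count": viral,
        "host_gene_count": host,
        "total_gene_count": total,
        "dvf_score": round(float(rng.uniform(0.91, 0.995)), 4),
        "dvf_pvalue": round(float(rng.uniform(1e-5, 0.009)), 6),
        "vibrant_viral": bool(rng.random() < 0.7),
        "busco_count": 0,
        "completeness": round(float(rng.uniform(55.0, 100.0)), 1),
        "contamination": round(float(rng.uniform(0.0, 9.0)), 1),
    }


def _decoy_rows(cfg: SimConfig) -> list[dict]:
    """Non-viral decoy contigs, cycling through every rejection mode."""
    rows = []
    kinds = ["too_short", "hostlike", "nonviral", "busco", "lowcomp"]
    for i in range(cfg.n_decoys):
        rng = child_rng(cfg.seed, "decoy", i)
        kind = kinds[i % len(kinds)]
        length = int(rng.integers(2500, 6000))
        row = {
            "contig_id": f"decoy{i + 1:03d}",
            "length": length,
            "viral_gene_count": 1,
            "host_gene_count": 0,
            "total_gene_count": 30,
            "dvf_score": 0.2,
            "dvf_pvalue": 0.5,
            "vibrant_viral": False,
            "busco_count": 0,
            "completeness": 80.0,
            "contamination": 2.0,
        }
        if kind == "too_short":
            row["length"] = int(rng.integers(500, 2001))
        elif kind == "hostlike":
            row.update(viral_gene_count=1, host_gene_count=15, total_gene_count=20)
        elif kind == "nonviral":
            row.update(viral_gene_count=2, host_gene_count=5, total_gene_count=10)
        elif kind == "busco":
            row.update(
                viral_gene_count=10,
                host_gene_count=2,
                total_gene_count=20,
                busco_count=3,
            )
        elif kind == "lowcomp":
            row.update(
                viral_gene_count=8, host_gene_count=1, total_gene_count=12,
                completeness=30.0,
            )
        rows.append(row)
    return rows


def _protein_hits(
    cfg: SimConfig,
    votus: list[str],
    families: list[str],
    gene_totals: dict[str, int],
) -> pd.DataFrame:
    rows = []
    for v, fam in zip(votus, families):
        rng = child_rng(cfg.seed, "prot", v)
        n_genes = gene_totals[v]
        if fam != "unclassified":
            if n_genes < 30:
                n_match = n_genes // 5 + 1 + int(rng.integers(0, 2))
            else:
                n_match = 10 + int(rng.integers(0, 4))
            n_match = min(n_match, n_genes)
            for k in range(n_match):
                rows.append(
                    {
                        "protein_id": f"{v}_p{k + 1}",
                        "votu_id": v,
                        "target_family": fam,
                        "percent_identity": round(float(rng.uniform(35, 95)), 1),
                        "query_coverage": round(float(rng.uniform(55, 98)), 1),
                        "subject_coverage": round(float(rng.uniform(55, 98)), 1),
                        "bit_score": round(float(rng.uniform(60, 300)), 1),
                    }
                )
        # sub-threshold noise hit: survives nothing
        if rng.random() < 0.5:
            rows.append(
                {
                    "protein_id": f"{v}_px",
                    "votu_id": v,
                    "target_family": _PROK_FAMILIES[rng.integers(len(_PROK_FAMILIES))],
                    "percent_identity": round(float(rng.uniform(10, 25)), 1),
                    "query_coverage": round(float(rng.uniform(10, 45)), 1),
                    "subject_coverage": round(float(rng.uniform(10, 45)), 1),
                    "bit_score": round(float(rng.uniform(20, 45)), 1),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "protein_id",
            "votu_id",
            "target_family",
            "percent_identity",
            "query_coverage",
            "subject_coverage",
            "bit_score",
        ],
    )


def _host_hits(
    cfg: SimConfig, votus: list[str], hosts: dict[str, str]
) -> tuple[list[dict], list[dict]]:
    spacer_rows, aln_rows = [], []
    for v in votus:
        rng = child_rng(cfg.seed, "hosthit", v)
        host = hosts[v]
        if host:
            genome_id = f"{host}_g{int(rng.integers(1, 50)):02d}"
            if rng.random() < 0.7:
                spacer_rows.append(
                    {
                        "votu_id": v,
                        "host_genome_id": genome_id,
                        "bit_score": round(float(rng.uniform(45, 120)), 1),
                    }
                )
            else:
                aln_rows.append(
                    {
                        "votu_id": v,
                        "host_genome_id": genome_id,
                        "percent_identity": round(float(rng.uniform(90, 99.9)), 2),
                        "viral_coverage": round(float(rng.uniform(0.30, 0.95)), 3),
                    }
                )
        elif rng.random() < 0.3:  # sub-threshold decoy evidence
            spacer_rows.append(
                {
                    "votu_id": v,
                    "host_genome_id": f"{_HOST_POOL[rng.integers(len(_HOST_POOL))]}_g99",
                    "bit_score": round(float(rng.uniform(20, 44.9)), 1),
                }
            )
    return spacer_rows, aln_rows


def _function_presence(
    cfg: SimConfig, votus: list[str], status: dict[str, str]
) -> pd.DataFrame:
    functions = [f"F{i + 1:03d}" for i in range(cfg.n_functions)]
    data = {}
    for v in votus:
        rng = child_rng(cfg.seed, "func", v)
        col = []
        for i in range(cfg.n_functions):
            if i < 5:
                p = 0.8 if status[v] == "case_enriched" else 0.05
            elif i < 10:
                p = 0.8 if status[v] == "control_enriched" else 0.05
            else:
                p = 0.3
            col.append(bool(rng.random() < p))
        data[v] = col
    frame = pd.DataFrame(data, index=functions)
    frame.index.name = "function_id"
    return frame
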