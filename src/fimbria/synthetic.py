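"""Seeded synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates a six-sample, two-group (carrier/control) fallopian-
tube mucosa cohort: five major cell types with marker-gene structure,
secretory/ciliated/transition epithelial subtypes driven by PAX8/TP73
detection, a planted EMT secretory subpopulation in one carrier sample,
EMT transcription-factor enrichment in carrier fibroblasts, a
mitochondrial-content tail to exercise QC, and a paired-TCR repertoire with
group-specific clonal expansion and PD-1/clonality coupling.

Counts are negative binomial (UMI overdispersion) around log-normal gene
base rates; all planted effects are multiplicative shifts of the mean on the
natural-log scale.  Everything is reproducible from a single seed.
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import ExpressionMatrix, TcrChainRecord, write_contigs, write_matrix_dir

__all__ = [
    "CohortConfig",
    "generate_expression",
    "generate_tcr",
    "generate_cohort",
    "generate_reference",
    "write_cohort",
]

MAJOR_TYPES = ("epithelial", "fibroblast", "T", "macrophage", "endothelial")

TYPE_MARKERS = {
    "epithelial": ("EPCAM", "KRT18"),
    "fibroblast": ("DCN",),
    "T": ("CD3D", "CD3E", "CD3G"),
    "macrophage": ("CD68",),
    "endothelial": ("PECAM1",),
}

MT_GENES = tuple(
    f"MT-{g}" for g in ("CO1", "CO2", "CO3", "ND1", "ND2", "ND3", "ND4", "ND4L",
                        "ND5", "ND6", "ATP6", "ATP8", "CYB")
)

EMT_PROGRAM = ("ZEB1", "ZEB2", "SFRP4", "DCN", "RGS16", "SERPINF1",
               "VIM", "FN1", "COL1A1", "COL3A1")
EMT_TFS_FIBRO = ("SNAI1", "SNAI2", "ZEB1", "TWIST2")

# reference secretory-subtype programs for the cluster-similarity stage
REFERENCE_PROGRAMS = {
    "cell-cycle": ("MKI67", "TOP2A", "CCNB1", "CDK1", "PCNA", "UBE2C"),
    "EMT": EMT_PROGRAM,
    "differentiated": ("OVGP1", "SLPI", "MUC1", "CRISP3", "LCN2", "WFDC2"),
    "KRT17": ("KRT17", "KRT5", "KRT6A", "KRT23", "S100A2", "TP63"),
}

SPECIAL_GENES = tuple(
    dict.fromkeys(
        [g for ms in TYPE_MARKERS.values() for g in ms]
        + ["PAX8", "TP73", "CD8A", "CD4"]
        + ["PDCD1", "HAVCR2", "LAG3", "CTLA4", "TOX", "ENTPD1"]
        + ["SNAI1", "SNAI2", "ZEB1", "ZEB2", "TWIST1", "TWIST2"]
        + [g for ms in REFERENCE_PROGRAMS.values() for g in ms]
    )
)

# beyond the marker panels, each major type expresses a broader program of
# type-specific genes (as real cell types do); clustering rides on these
TYPE_PROGRAM_SIZE = 30
TYPE_PROGRAM_GENES = {
    t: tuple(f"{t.upper()}PROG{i:02d}" for i in range(1, TYPE_PROGRAM_SIZE + 1))
    for t in MAJOR_TYPES
}

AA = "ACDEFGHIKLMNPQRSTVWY"
NT = "ACGT"

TRA_V = ("TRAV1-2", "TRAV8-2", "TRAV12-1", "TRAV21", "TRAV29")
TRA_J = ("TRAJ33", "TRAJ20", "TRAJ49")
TRB_V = ("TRBV19", "TRBV5-1", "TRBV20-1", "TRBV7-9", "TRBV28")
TRB_J = ("TRBJ2-1", "TRBJ1-2", "TRBJ2-7")


@dataclass(frozen=True)
class CohortConfig:
    """Cohort design and effect sizes.

    Proportions mirror the study design (five types with a ~17% T-cell
    compartment; secretory-dominated epithelium); clonal fractions default
    to 0.73 (carrier) / 0.62 (control), the fractions implied by the
    printed clonal/non-clonal counts 672/242 and 337/210.  Effects are
    natural-log mean shifts.
    """

    n_samples_per_group: int = 3
    cells_per_sample: int = 500
    n_genes: int = 2000
    library_size: float = 1000.0
    nb_dispersion: float = 2.0  # NB inverse-dispersion (size); smaller = noisier
    type_proportions: tuple[float, ...] = (0.45, 0.25, 0.17, 0.08, 0.05)
    subtype_proportions: tuple[float, float, float] = (0.65, 0.25, 0.10)  # secretory/ciliated/transition
    marker_effect: float = 2.5
    marker_base_mean: float = 0.02
    type_program_effect: float = 1.5
    type_program_base_mean: float = 0.2
    high_mito_fraction: float = 0.05
    mito_weight: float = 0.05  # share of the library on MT- genes in healthy cells
    emt_host_sample: str = "carrier_1"
    emt_fraction_of_secretory: float = 0.25
    emt_effect: float = 2.0
    fibro_emt_base_mean: float = 0.09
    fibro_emt_effect: float = 1.0
    cd8_fraction_of_t: float = 0.6
    clonal_fraction: tuple[float, float] = (0.73, 0.62)  # carrier, control
    clone_size_geom_p: float = 0.5
    pd1_coupling: float = 1.0
    pd1_carrier_shift: float = 0.5
    exhaustion_base_mean: float = 0.3
    unpaired_fraction: float = 0.05
    nonproductive_fraction: float = 0.05

    def __post_init__(self) -> None:
        if abs(sum(self.type_proportions) - 1.0) > 1e-9:
            raise ValueError("type proportions must sum to 1")
        if abs(sum(self.subtype_proportions) - 1.0) > 1e-9:
            raise ValueError("epithelial subtype proportions must sum to 1")
        for f in (*self.clonal_fraction, self.emt_fraction_of_secretory,
                  self.high_mito_fraction, self.cd8_fraction_of_t,
                  self.unpaired_fraction, self.nonproductive_fraction):
            if not (0.0 <= f <= 1.0):
                raise ValueError("fractions must lie in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        n_named = len(SPECIAL_GENES) + len(MT_GENES) + len(MAJOR_TYPES) * TYPE_PROGRAM_SIZE
        if self.n_genes < n_named + 50:
            raise ValueError(f"n_genes must be at least {n_named + 50}")


def _gene_space(config: CohortConfig, rng: np.random.Generator):
    """Gene symbols and base mean counts per cell.

    Named genes (markers, programs, MT-) get fixed base means; filler genes
    draw log-normal rates scaled so the expected healthy-cell library is
    ``library_size``.
    """
    program_genes = [g for t in MAJOR_TYPES for g in TYPE_PROGRAM_GENES[t]]
    symbols = list(SPECIAL_GENES) + list(MT_GENES) + program_genes
    n_named = len(symbols)
    n_filler = config.n_genes - n_named
    symbols += [f"GENE{i:05d}" for i in range(1, n_filler + 1)]
    ids = [f"SYN{i:05d}" for i in range(1, config.n_genes + 1)]

    base = np.full(config.n_genes, config.marker_base_mean)
    idx = {s: i for i, s in enumerate(symbols)}
    mito_total = config.mito_weight * config.library_size
    for g in MT_GENES:
        base[idx[g]] = mito_total / len(MT_GENES)
    for g in program_genes:
        base[idx[g]] = config.type_program_base_mean
    filler_total = (
        config.library_size
        - mito_total
        - config.marker_base_mean * len(SPECIAL_GENES)
        - config.type_program_base_mean * len(program_genes)
    )
    w = rng.lognormal(mean=0.0, sigma=1.3, size=n_filler)
    base[n_named:] = w / w.sum() * max(filler_total, 1.0)
    return symbols, ids, base, idx


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, theta: float) -> np.ndarray:
    p = theta / (theta + mean)
    return rng.negative_binomial(theta, p)


def _sample_names(config: CohortConfig) -> list[tuple[str, str]]:
    names = []
    for group in ("carrier", "control"):
        for i in range(1, config.n_samples_per_group + 1):
            names.append((f"{group}_{i}", group))
    return names


def generate_expression(
    config: CohortConfig = CohortConfig(), seed: int = 0
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Synthesize the cohort count matrix and per-cell truth labels.

    Truth columns: barcode, sample, group, major_type, epithelial_subtype,
    emt_member, is_cd8, high_mito.
    """
    rng = np.random.default_rng(seed)
    symbols, ids, base, idx = _gene_space(config, rng)
    theta = config.nb_dispersion

    cells: list[dict] = []
    col_means: list[np.ndarray] = []

    for sample, group in _sample_names(config):
        n = config.cells_per_sample
        types = rng.choice(MAJOR_TYPES, size=n, p=config.type_proportions)
        for j in range(n):
            major = str(types[j])
            mean = base.copy()
            for m in TYPE_MARKERS[major]:
                # marker shift, floored for reliable detection in the own type
                mean[idx[m]] = max(mean[idx[m]] * math.exp(config.marker_effect), 2.0)
            for g in TYPE_PROGRAM_GENES[major]:
                mean[idx[g]] *= math.exp(config.type_program_effect)

            subtype = "not_applicable"
            emt_member = False
            is_cd8 = False
            if major == "epithelial":
                subtype = str(
                    rng.choice(("secretory", "ciliated", "transition"), p=config.subtype_proportions)
                )
                if subtype in ("secretory", "transition"):
                    mean[idx["PAX8"]] = 3.0
                if subtype in ("ciliated", "transition"):
                    mean[idx["TP73"]] = 3.0
                if (
                    subtype == "secretory"
                    and sample == config.emt_host_sample
                    and rng.random() < config.emt_fraction_of_secretory
                ):
                    emt_member = True
                    for g in EMT_PROGRAM:
                        mean[idx[g]] = max(mean[idx[g]], 0.3) * math.exp(config.emt_effect)
            elif major == "fibroblast":
                for g in EMT_TFS_FIBRO:
                    mean[idx[g]] = config.fibro_emt_base_mean
                    if group == "carrier":
                        mean[idx[g]] *= math.exp(config.fibro_emt_effect)
            elif major == "T":
                is_cd8 = bool(rng.random() < config.cd8_fraction_of_t)
                mean[idx["CD8A" if is_cd8 else "CD4"]] = 3.0
                for g in ("PDCD1", "HAVCR2", "LAG3", "CTLA4", "TOX", "ENTPD1"):
                    mean[idx[g]] = config.exhaustion_base_mean

            high_mito = bool(rng.random() < config.high_mito_fraction)
            if high_mito:
                boost = rng.uniform(5.0, 15.0)
                for g in MT_GENES:
                    mean[idx[g]] *= boost
            # per-cell depth variation
            mean *= rng.lognormal(0.0, 0.3)

            cells.append(
                {
                    "barcode": f"{sample}-{j + 1:05d}",
                    "sample": sample,
                    "group": group,
                    "major_type": major,
                    "epithelial_subtype": subtype,
                    "emt_member": emt_member,
                    "is_cd8": is_cd8,
                    "high_mito": high_mito,
                }
            )
            col_means.append(mean)

    means = np.column_stack(col_means)  # genes x cells
    counts = _nb_draw(rng, means, theta)
    truth = pd.DataFrame(cells)
    matrix = ExpressionMatrix(
        counts=sp.csr_matrix(counts),
        gene_ids=ids,
        gene_symbols=symbols,
        barcodes=truth["barcode"].tolist(),
        sample_of_cell=truth["sample"].to_numpy(dtype=object),
        group_of_cell=truth["group"].to_numpy(dtype=object),
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# TCR repertoire
# ---------------------------------------------------------------------------

def _fresh_cdr3(rng: np.random.Generator, used: set[str]) -> tuple[str, str]:
    while True:
        length = int(rng.integers(8, 21))
        aa = "C" + "".join(rng.choice(list(AA), size=length - 2)) + "F"
        if aa not in used:
            used.add(aa)
            nt = "".join(rng.choice(list(NT), size=3 * length))
            return aa, nt


def _partition_clones(n_clonal: int, geom_p: float, rng: np.random.Generator) -> list[int]:
    """Clone sizes >= 2 summing exactly to n_clonal (geometric tail)."""
    if n_clonal < 2:
        return []
    sizes: list[int] = []
    remaining = n_clonal
    while remaining >= 2:
        s = 2 + int(rng.geometric(geom_p)) - 1  # support {2, 3, ...}
        s = min(s, remaining)
        if remaining - s == 1:  # never strand a single cell
            s += 1
        sizes.append(s)
        remaining -= s
    return sizes


def generate_tcr(
    config: CohortConfig,
    seed: int,
    t_cells: pd.DataFrame,
) -> tuple[list[TcrChainRecord], pd.DataFrame]:
    """Paired-TCR contigs for the cohort's T cells plus per-cell clonal truth.

    ``t_cells`` needs columns barcode, group, is_cd8.  Per group, the
    configured clonal fraction of CD8+ cells is placed in clones of
    geometric size >= 2 and the rest in singletons; CD4 cells are singletons.
    A configurable fraction of CD4 cells emit only a TRA (exercising the
    pairing filter) and some cells emit an extra non-productive contig.
    """
    if t_cells.empty:
        raise ValueError("no T cells to build a repertoire from")
    rng = np.random.default_rng(seed)
    used: set[str] = set()
    records: list[TcrChainRecord] = []
    rows: list[dict] = []

    def emit(barcode: str, pair: tuple[tuple[str, str], tuple[str, str]], drop_trb: bool) -> None:
        (tra_aa, tra_nt), (trb_aa, trb_nt) = pair
        records.append(
            TcrChainRecord(barcode, "TRA", str(rng.choice(TRA_V)), str(rng.choice(TRA_J)),
                           tra_aa, tra_nt, int(rng.integers(2, 30)), True, True, True)
        )
        if not drop_trb:
            records.append(
                TcrChainRecord(barcode, "TRB", str(rng.choice(TRB_V)), str(rng.choice(TRB_J)),
                               trb_aa, trb_nt, int(rng.integers(2, 30)), True, True, True)
            )
        if rng.random() < config.nonproductive_fraction:
            aa, nt = _fresh_cdr3(rng, used)
            records.append(
                TcrChainRecord(barcode, "TRA", str(rng.choice(TRA_V)), str(rng.choice(TRA_J)),
                               aa, nt, 1, False, True, True)
            )

    for group, frac in zip(("carrier", "control"), config.clonal_fraction):
        sub = t_cells[(t_cells["group"] == group)]
        cd8 = sub[sub["is_cd8"]]["barcode"].tolist()
        cd4 = sub[~sub["is_cd8"]]["barcode"].tolist()
        cd8 = [cd8[i] for i in rng.permutation(len(cd8))]
        n_clonal = int(round(frac * len(cd8)))
        if frac == 1.0 and n_clonal < 2:
            raise ValueError("clonal fraction 1.0 requires at least 2 CD8 cells")
        sizes = _partition_clones(n_clonal, config.clone_size_geom_p, rng)
        pos = 0
        for s in sizes:
            pair = (_fresh_cdr3(rng, used), _fresh_cdr3(rng, used))
            for barcode in cd8[pos:pos + s]:
                emit(barcode, pair, drop_trb=False)
                rows.append({"barcode": barcode, "group": group, "planted_clonal": True})
            pos += s
        for barcode in cd8[pos:]:
            pair = (_fresh_cdr3(rng, used), _fresh_cdr3(rng, used))
            emit(barcode, pair, drop_trb=False)
            rows.append({"barcode": barcode, "group": group, "planted_clonal": False})
        for barcode in cd4:
            pair = (_fresh_cdr3(rng, used), _fresh_cdr3(rng, used))
            drop = rng.random() < config.unpaired_fraction
            emit(barcode, pair, drop_trb=drop)
            rows.append({"barcode": barcode, "group": group, "planted_clonal": False})

    return records, pd.DataFrame(rows)


def _apply_pd1_coupling(
    matrix: ExpressionMatrix,
    truth: pd.DataFrame,
    tcr_truth: pd.DataFrame,
    config: CohortConfig,
    rng: np.random.Generator,
) -> None:
    """Redraw PDCD1 counts of planted-clonal cells with an up-shifted mean."""
    clonal_barcodes = set(tcr_truth[tcr_truth["planted_clonal"]]["barcode"])
    if not clonal_barcodes:
        return
    row = matrix.gene_row("PDCD1")
    counts = matrix.counts.tolil()
    for col, (barcode, group) in enumerate(zip(matrix.barcodes, matrix.group_of_cell)):
        if barcode not in clonal_barcodes:
            continue
        shift = config.pd1_coupling + (config.pd1_carrier_shift if group == "carrier" else 0.0)
        mean = config.exhaustion_base_mean * math.exp(shift)
        counts[row, col] = int(_nb_draw(rng, np.array([mean]), config.nb_dispersion)[0])
    matrix.counts = sp.csr_matrix(counts)


def generate_cohort(
    config: CohortConfig = CohortConfig(), seed: int = 0
) -> tuple[ExpressionMatrix, list[TcrChainRecord], pd.DataFrame]:
    """Full cohort: expression matrix, TCR contigs and joined truth labels."""
    matrix, truth = generate_expression(config, seed)
    t_cells = truth[truth["major_type"] == "T"][["barcode", "group", "is_cd8"]]
    contigs, tcr_truth = generate_tcr(config, seed + 1, t_cells)
    rng = np.random.default_rng(seed + 2)
    _apply_pd1_coupling(matrix, truth, tcr_truth, config, rng)
    truth = truth.merge(
        tcr_truth[["barcode", "planted_clonal"]], on="barcode", how="left"
    )
    truth["planted_clonal"] = np.array(
        [bool(v) if pd.notna(v) else False for v in truth["planted_clonal"]], dtype=bool
    )
    return matrix, contigs, truth


def generate_reference(
    config: CohortConfig = CohortConfig(),
    seed: int = 0,
    n_per_subtype: int = 50,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Reference secretory-subtype cells on the cohort's gene space.

    Synthetic stand-in for an external secretory-cell reference atlas: four
    subtypes (cell-cycle, EMT, differentiated, KRT17), each with its program
    genes up-shifted.  Returns (raw counts cells x genes, subtype labels,
    gene symbols).
    """
    rng = np.random.default_rng(seed)
    symbols, _, base, idx = _gene_space(config, rng)
    labels: list[str] = []
    cols: list[np.ndarray] = []
    for subtype, program in REFERENCE_PROGRAMS.items():
        for _ in range(n_per_subtype):
            mean = base.copy()
            mean[idx["PAX8"]] = 3.0  # secretory reference cells
            for m in TYPE_MARKERS["epithelial"]:
                mean[idx[m]] = max(mean[idx[m]] * math.exp(config.marker_effect), 2.0)
            for g in TYPE_PROGRAM_GENES["epithelial"]:
                mean[idx[g]] *= math.exp(config.type_program_effect)
            for g in program:
                mean[idx[g]] = max(mean[idx[g]], 0.3) * math.exp(config.emt_effect)
            mean *= rng.lognormal(0.0, 0.3)
            cols.append(_nb_draw(rng, mean, config.nb_dispersion))
            labels.append(subtype)
    counts = np.column_stack(cols).T  # cells x genes
    return counts, np.array(labels, dtype=object), symbols


def write_cohort(
    config: CohortConfig,
    seed: int,
    out_dir: str | Path,
) -> Path:
    """Emit per-sample MTX directories, per-sample contig CSVs and truth TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix, contigs, truth = generate_cohort(config, seed)
    for sample in pd.unique(matrix.sample_of_cell):
        sub = matrix.subset_cells(matrix.sample_of_cell == sample)
        write_matrix_dir(sub, out / sample)
        sample_barcodes = set(sub.barcodes)
        write_contigs(
            [c for c in contigs if c.barcode in sample_barcodes],
            out / sample / "filtered_contig_annotations.csv",
        )
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    return out
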