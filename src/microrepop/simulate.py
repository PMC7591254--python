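"""Synthetic scRNA-seq count matrices emulating microglial repopulation data.

The generator plants a known nine-population structure — five myeloid
clusters (homeostatic, chemokine, ribosomal/translation, MHC/Cd74-high,
proliferative) plus four contaminant populations (neutrophil, lymphoid,
endothelial, astroglial) — across three experimental conditions (untreated
Ctrl; D0, end of a two-week CSF1R-inhibitor course; D2, two days of
repopulation). A configurable fraction of myeloid cells additionally carry a
Galectin-3 (Lgals3)-high immature program: yolk-sac / early-embryonic genes
and Lyz2 shifted up, homeostatic markers (Tmem119, P2ry12, Cx3cr1, Csf1r,
Mafb) shifted down. Counts are negative binomial around per-cell means built
from a gamma-distributed gene baseline, population-specific marker panels,
a beta-distributed mitochondrial fraction, and lognormal library sizes.

Every downstream stage (QC, clustering, gating, differential expression,
abundance testing) is exercised against the ground-truth labels this module
records.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

CONDITIONS = ("Ctrl", "D0", "D2")

MYELOID_POPULATIONS = (
    "homeostatic",
    "chemokine",
    "ribosomal",
    "mhc",
    "proliferative",
)
CONTAMINANT_POPULATIONS = ("neutrophil", "lymphoid", "endothelial", "astroglial")
POPULATIONS = MYELOID_POPULATIONS + CONTAMINANT_POPULATIONS

STAGE_NAMES = ("YS", "E1", "E2", "P1", "P2", "A1", "A2")

# Marker symbols seeding each panel; panels are padded with synthetic gene ids.
_PANEL_SEEDS = {
    "homeostatic": [
        "Tmem119", "P2ry12", "P2ry13", "Selplg", "Cx3cr1", "Csf1r",
        "Trem2", "Mafb", "Hexb", "Siglech",
    ],
    "chemokine": ["Ccl3", "Ccl4", "Ccl2", "Egr1", "Nfkbia", "Tnf"],
    "ribosomal": ["Lars2", "Dst", "Macf1", "Rps26", "Rps8", "Rpl13a"],
    "mhc": ["Cd74", "H2-Ab1", "H2-Eb1", "H2-Aa", "B2m"],
    "proliferative": ["Mki67", "Top2a", "Stmn1", "Ube2c", "Ccnb1"],
    "neutrophil": ["S100a8", "S100a9", "Ly6g", "Retnlg"],
    "lymphoid": ["Cd3e", "Cd19", "Nkg7", "Ms4a1"],
    "endothelial": ["Cldn5", "Pecam1", "Flt1"],
    "astroglial": ["Gfap", "Aqp4", "Slc1a3"],
}

MYELOID_CORE_PANEL = ("Itgam", "Aif1", "Cx3cr1", "Csf1r")

MITO_GENES = [
    "mt-Nd1", "mt-Nd2", "mt-Co1", "mt-Co2", "mt-Atp8", "mt-Atp6", "mt-Co3",
    "mt-Nd3", "mt-Nd4l", "mt-Nd4", "mt-Nd5", "mt-Nd6", "mt-Cytb",
]


@dataclass
class GenParams:
    """Parameters of the synthetic-count generator.

    ``cluster_props`` maps condition -> {population -> probability}; each
    vector must sum to one. ``mac2_frac`` is the per-condition probability
    that a myeloid cell carries the Lgals3-high immature program.
    ``nb_dispersion`` is the negative-binomial size parameter
    (variance = mu + mu^2 / size). ``effect_logfc`` is the natural-log fold
    shift applied to program genes in program-carrying cells.
    """

    n_genes: int = 2000
    panels: dict[str, list[str]] = field(default_factory=dict)
    cluster_props: dict[str, dict[str, float]] = field(default_factory=dict)
    mac2_frac: dict[str, float] = field(default_factory=dict)
    libsize_meanlog: float = math.log(5000.0)
    libsize_sdlog: float = 0.35
    nb_dispersion: float = 8.0
    effect_logfc: float = 1.5
    panel_logfc: float = 2.3
    n_cells_per_sample: int = 1000
    samples_per_condition: dict[str, int] = field(
        default_factory=lambda: {"Ctrl": 3, "D0": 3, "D2": 2}
    )
    mito_mean_frac: float = 0.04
    mito_high_frac: float = 0.03
    mito_high_mean: float = 0.16
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.n_cells_per_sample <= 0:
            raise ValueError("n_cells_per_sample must be positive")
        for cond, props in self.cluster_props.items():
            total = sum(props.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"cluster_props for {cond!r} sum to {total}, expected 1"
                )
            if any(p < 0 for p in props.values()):
                raise ValueError(f"negative population probability in {cond!r}")
        for cond, frac in self.mac2_frac.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"mac2_frac[{cond!r}]={frac} outside [0, 1]")
        universe = set(gene_universe(self.n_genes, self.panels))
        for name, genes in self.panels.items():
            missing = set(genes) - universe
            if missing:
                raise ValueError(
                    f"panel {name!r} references genes outside the universe: "
                    f"{sorted(missing)[:5]}"
                )
        stage_seen: dict[str, str] = {}
        for stage in STAGE_NAMES:
            for g in self.panels.get(f"stage_{stage}", []):
                if g in stage_seen:
                    raise ValueError(
                        f"gene {g!r} in both stage_{stage_seen[g]} and stage_{stage}"
                    )
                stage_seen[g] = stage
        if self.effect_logfc != 0:
            for key in ("lgals3_program_up", "lgals3_program_down"):
                if not self.panels.get(key):
                    raise ValueError(
                        f"effect_logfc is nonzero but panel {key!r} is empty"
                    )


@dataclass
class CountMatrix:
    """Sparse genes x cells integer counts with cell and gene metadata.

    ``cell_meta`` rows align with matrix columns (cell_id, sample_id,
    condition, true_population, true_mac2, plus any labels added
    downstream); ``gene_meta`` rows align with matrix rows (gene_id,
    is_mito, panels).
    """

    counts: sp.csr_matrix
    cell_meta: pd.DataFrame
    gene_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.shape[1] != len(self.cell_meta):
            raise ValueError("cell_meta rows must match matrix columns")
        if self.counts.shape[0] != len(self.gene_meta):
            raise ValueError("gene_meta rows must match matrix rows")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def subset_cells(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return CountMatrix(
            counts=self.counts[:, idx].tocsr(),
            cell_meta=self.cell_meta.iloc[idx].reset_index(drop=True),
            gene_meta=self.gene_meta.copy(),
        )

    def subset_genes(self, mask: np.ndarray) -> "CountMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return CountMatrix(
            counts=self.counts[idx, :].tocsr(),
            cell_meta=self.cell_meta.copy(),
            gene_meta=self.gene_meta.iloc[idx].reset_index(drop=True),
        )


def gene_universe(n_genes: int, panels: dict[str, list[str]]) -> list[str]:
    """Ordered gene-id list: named panel genes first, synthetic filler after."""
    named: list[str] = []
    seen = set()
    for genes in panels.values():
        for g in genes:
            if g not in seen:
                seen.add(g)
                named.append(g)
    for g in MITO_GENES + list(MYELOID_CORE_PANEL):
        if g not in seen:
            seen.add(g)
            named.append(g)
    if "Lgals3" not in seen:
        named.append("Lgals3")
        seen.add("Lgals3")
    filler = [f"Gene{i:05d}" for i in range(max(0, n_genes - len(named)))]
    return (named + filler)[:n_genes] if n_genes >= len(named) else named


def default_panels(n_genes: int = 2000) -> dict[str, list[str]]:
    """Deterministic default panels over a universe of ``n_genes`` genes.

    Population panels carry their canonical markers plus synthetic filler;
    the seven developmental stage sets are pairwise disjoint; the Lgals3-high
    program pulls from YS and E1 (up) and from homeostatic markers (down) so
    that signature-overlap scoring sees the same structure the real data do.
    """
    panels: dict[str, list[str]] = {}
    cursor = 0

    def take(n: int) -> list[str]:
        nonlocal cursor
        ids = [f"Gene{i:05d}" for i in range(cursor, cursor + n)]
        cursor += n
        return ids

    for name, seeds in _PANEL_SEEDS.items():
        pad = 25 if name in MYELOID_POPULATIONS else 20
        panels[name] = list(seeds) + take(pad - len(seeds))
    panels["mito"] = list(MITO_GENES)

    # Disjoint developmental stage sets.  A1/A2 absorb the homeostatic
    # markers (split between them), mirroring adult microglia signatures.
    panels["stage_YS"] = take(30)
    panels["stage_E1"] = ["Lyz2"] + take(29)
    panels["stage_E2"] = take(30)
    panels["stage_P1"] = take(30)
    panels["stage_P2"] = take(30)
    panels["stage_A1"] = ["Tmem119", "P2ry12", "Mafb"] + take(27)
    panels["stage_A2"] = ["Cx3cr1", "Csf1r", "Selplg"] + take(27)

    # The immature program: Lgals3 itself, Lyz2, a YS slice, an E1 slice,
    # and some unassigned genes (up); homeostatic markers (down).
    panels["lgals3_program_up"] = (
        ["Lgals3", "Lyz2"]
        + panels["stage_YS"][:12]
        + panels["stage_E1"][1:26]
        + take(14)
    )
    panels["lgals3_program_down"] = [
        "Tmem119", "P2ry12", "Cx3cr1", "Csf1r", "Mafb", "Selplg",
    ]
    panels["myeloid"] = list(MYELOID_CORE_PANEL)
    return panels


def default_cluster_props() -> dict[str, dict[str, float]]:
    """Per-condition population proportions mirroring the study's shifts.

    Ctrl is dominated by homeostatic cells with proliferative cells at
    0.12%; the inhibitor-treated (D0) and early-repopulation (D2) brains
    shift toward chemokine/MHC and proliferative states (~10%).  Each
    condition carries ~9% contaminants so contaminant stripping has work
    to do.
    """
    contam = {p: 0.0225 for p in CONTAMINANT_POPULATIONS}

    def norm(myeloid: dict[str, float]) -> dict[str, float]:
        props = {**myeloid, **contam}
        total = sum(props.values())
        return {k: v / total for k, v in props.items()}

    return {
        "Ctrl": norm(
            {
                "homeostatic": 0.60,
                "chemokine": 0.13,
                "ribosomal": 0.10,
                "mhc": 0.078,
                "proliferative": 0.0012,
            }
        ),
        "D0": norm(
            {
                "homeostatic": 0.24,
                "chemokine": 0.28,
                "ribosomal": 0.12,
                "mhc": 0.17,
                "proliferative": 0.10,
            }
        ),
        "D2": norm(
            {
                "homeostatic": 0.22,
                "chemokine": 0.20,
                "ribosomal": 0.25,
                "mhc": 0.14,
                "proliferative": 0.10,
            }
        ),
    }


def default_mac2_frac() -> dict[str, float]:
    # Observed MAC2+ frequencies: 3.0% Ctrl, 9.8% D0, 11.2% D2.
    return {"Ctrl": 0.030, "D0": 0.098, "D2": 0.112}


def default_params(**overrides) -> GenParams:
    """GenParams at the study's default conditions."""
    n_genes = int(overrides.pop("n_genes", 2000))
    params = GenParams(
        n_genes=n_genes,
        panels=default_panels(n_genes),
        cluster_props=default_cluster_props(),
        mac2_frac=default_mac2_frac(),
    )
    return replace(params, **overrides) if overrides else params


def _population_weights(
    genes: list[str], panels: dict[str, list[str]], panel_logfc: float, rng
) -> tuple[np.ndarray, np.ndarray]:
    """Baseline gene means and per-population multiplier matrix."""
    n = len(genes)
    index = {g: i for i, g in enumerate(genes)}
    baseline = rng.gamma(shape=0.45, scale=1.0, size=n) + 0.01

    mult = np.ones((n, len(POPULATIONS)))
    boost = math.exp(panel_logfc)
    for j, pop in enumerate(POPULATIONS):
        for g in panels.get(pop, []):
            mult[index[g], j] *= boost
    # Myeloid core markers: robustly expressed in myeloid populations,
    # nearly absent from contaminants.
    for g in panels.get("myeloid", MYELOID_CORE_PANEL):
        if g not in index:
            continue
        i = index[g]
        for j, pop in enumerate(POPULATIONS):
            if pop in MYELOID_POPULATIONS:
                mult[i, j] *= 12.0
            else:
                mult[i, j] *= 0.02
    # Homeostatic markers stay detectable in every myeloid population
    # (reduced outside the homeostatic cluster, not silenced).
    for g in panels.get("homeostatic", []):
        i = index[g]
        for j, pop in enumerate(MYELOID_POPULATIONS):
            if pop != "homeostatic":
                mult[i, j] *= 3.0
        for j in range(len(MYELOID_POPULATIONS), len(POPULATIONS)):
            mult[i, j] *= 0.05
    # Lgals3 is the gate-defining marker: pin its baseline to a moderate,
    # reliably detected level (the real marker is expressed across clusters)
    # instead of leaving it to the gamma draw.
    if "Lgals3" in index:
        baseline[index["Lgals3"]] = 2.0
    return baseline, mult


def generate_counts(params: GenParams) -> CountMatrix:
    """Draw a synthetic count matrix with ground-truth labels.

    Per cell: population from the condition's proportions; an Lgals3-program
    flag for myeloid cells with probability ``mac2_frac``; gene means =
    baseline x population multipliers x program shifts, mitochondrial genes
    rescaled to a beta-distributed per-cell fraction; means normalised to a
    lognormal library size; counts ~ NB(mean, size) via gamma-Poisson
    mixing. Deterministic given ``params.seed``.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    genes = gene_universe(params.n_genes, params.panels)
    n_genes = len(genes)
    index = {g: i for i, g in enumerate(genes)}

    baseline, mult = _population_weights(
        genes, params.panels, params.panel_logfc, rng
    )

    mito_idx = np.array(
        [index[g] for g in params.panels.get("mito", MITO_GENES) if g in index],
        dtype=int,
    )
    is_mito = np.zeros(n_genes, dtype=bool)
    is_mito[mito_idx] = True

    up_idx = np.array(
        [index[g] for g in params.panels.get("lgals3_program_up", [])], dtype=int
    )
    down_idx = np.array(
        [index[g] for g in params.panels.get("lgals3_program_down", [])], dtype=int
    )

    # Per-cell draws, sample by sample.
    cells_rows = []
    blocks: list[sp.csr_matrix] = []
    pop_index = {p: j for j, p in enumerate(POPULATIONS)}
    cell_counter = 0
    for condition in CONDITIONS:
        n_samples = params.samples_per_condition.get(condition, 0)
        props = params.cluster_props[condition]
        prob = np.array([props.get(p, 0.0) for p in POPULATIONS])
        mfrac = params.mac2_frac.get(condition, 0.0)
        for s in range(n_samples):
            sample_id = f"{condition}_{s + 1}"
            n_cells = params.n_cells_per_sample
            pops = rng.choice(len(POPULATIONS), size=n_cells, p=prob)
            myeloid = pops < len(MYELOID_POPULATIONS)
            mac2 = myeloid & (rng.random(n_cells) < mfrac)
            libsize = rng.lognormal(
                params.libsize_meanlog, params.libsize_sdlog, size=n_cells
            )
            # Per-cell mitochondrial fraction; a small tail of stressed cells
            # exceeds the 10% QC cut-off.
            lo = rng.beta(4.0, 4.0 * (1 - params.mito_mean_frac) / params.mito_mean_frac, n_cells)
            hi = rng.beta(8.0, 8.0 * (1 - params.mito_high_mean) / params.mito_high_mean, n_cells)
            high = rng.random(n_cells) < params.mito_high_frac
            mito_frac = np.where(high, hi, lo)

            block = _sample_counts(
                rng, baseline, mult, pops, mac2, libsize, mito_frac,
                mito_idx, up_idx, down_idx,
                params.effect_logfc, params.nb_dispersion,
            )
            blocks.append(block)
            for i in range(n_cells):
                cells_rows.append(
                    (
                        f"CELL{cell_counter + i:07d}",
                        sample_id,
                        condition,
                        POPULATIONS[pops[i]],
                        bool(mac2[i]),
                    )
                )
            cell_counter += n_cells

    counts = sp.hstack(blocks, format="csr") if blocks else sp.csr_matrix((n_genes, 0))
    cell_meta = pd.DataFrame(
        cells_rows,
        columns=["cell_id", "sample_id", "condition", "true_population", "true_mac2"],
    )
    panel_membership = [set() for _ in range(n_genes)]
    for name, members in params.panels.items():
        for g in members:
            if g in index:
                panel_membership[index[g]].add(name)
    gene_meta = pd.DataFrame(
        {
            "gene_id": genes,
            "is_mito": is_mito,
            "panels": [";".join(sorted(p)) for p in panel_membership],
        }
    )
    return CountMatrix(counts=counts, cell_meta=cell_meta, gene_meta=gene_meta)


def _sample_counts(
    rng, baseline, mult, pops, mac2, libsize, mito_frac,
    mito_idx, up_idx, down_idx, effect_logfc, size,
) -> sp.csr_matrix:
    """NB counts for one sample, chunked over cells to bound memory."""
    n_genes = baseline.shape[0]
    n_cells = pops.shape[0]
    nonmito = np.ones(n_genes, dtype=bool)
    nonmito[mito_idx] = False
    up_shift = math.exp(effect_logfc)
    down_shift = math.exp(-effect_logfc)

    out = []
    chunk = 2048
    for start in range(0, n_cells, chunk):
        stop = min(start + chunk, n_cells)
        w = (baseline[:, None] * mult[:, pops[start:stop]]).astype(np.float64)
        m = mac2[start:stop]
        if m.any():
            cols = np.flatnonzero(m)
            if up_idx.size:
                w[np.ix_(up_idx, cols)] *= up_shift
            if down_idx.size:
                w[np.ix_(down_idx, cols)] *= down_shift
        # Rescale so mito genes carry exactly the drawn per-cell fraction.
        s_non = w[nonmito].sum(axis=0)
        f = mito_frac[start:stop]
        w[nonmito] *= (1.0 - f) / s_non
        if mito_idx.size:
            s_mit = w[mito_idx].sum(axis=0)
            w[mito_idx] *= f / np.where(s_mit > 0, s_mit, 1.0)
        mu = w * libsize[start:stop][None, :]
        lam = rng.gamma(shape=size, scale=mu / size)
        counts = rng.poisson(lam).astype(np.int32)
        out.append(sp.csr_matrix(counts))
    return sp.hstack(out, format="csr") if out else sp.csr_matrix((n_genes, 0))


def stage_sets_from_panels(panels: dict[str, list[str]]) -> dict[str, list[str]]:
    """Extract the seven developmental stage gene sets from a panel map."""
    out = {}
    for stage in STAGE_NAMES:
        key = f"stage_{stage}"
        if key not in panels:
            raise KeyError(f"panels lack {key!r}")
        out[stage] = list(panels[key])
    return out
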