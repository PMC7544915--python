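"""Two-layer, two-cohort synthetic count datasets with planted structure.

The generator emulates the shape of a two-layer heifer-fertility cohort: an mRNA layer and a
miRNA layer over the same animals, three pregnancy-outcome groups (6/6/5 by
default) and optionally two sampling years. Counts are negative-binomial
(gamma-Poisson) around log-scale means composed of

    baseline + group effect (planted DE) + year effect + latent signal,

where the latent signal plants coexpression structure. Planted correlations
are constructed on the *realized* sample scale: within the focal group the
two latent vectors of an edge are built with their empirical correlation
exactly equal to the target, and within reference groups they are built
empirically orthogonal. This matters because at n = 5-6 the sample
correlation of independent vectors has a standard deviation near 0.45, so
population-level planting could never satisfy the strict -0.1 < r < 0.1
absence band reliably. Count-level noise attenuates the planted correlation
by roughly s^2 / (s^2 + phi + 1/mean) for latent signal variance s^2;
planted-edge features therefore default to high abundance and low
dispersion, and the expected attenuation is recorded in the truth tables.

Truth tables record every planted effect so recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import CountMatrix, FeatureAnnotation, Layer, Outcome, SampleTable

__all__ = [
    "PlantedEdge",
    "PlantedCrossPair",
    "PlantedDEGene",
    "SimulationSpec",
    "SimulatedDataset",
    "simulate_dataset",
    "export_fixture",
    "null_spec",
    "planted_rewiring_spec",
    "two_year_spec",
]

_FOCAL = Outcome.NON_PREG.value
_REFS = (Outcome.AI_PREG.value, Outcome.NB_PREG.value)


@dataclass(frozen=True)
class PlantedEdge:
    """A gene pair planted to satisfy one rewiring class (focal group
    non-pregnant)."""

    feature_a: str
    feature_b: str
    rewire_class: str = "GAINED_POSITIVE"
    r_target: float = 0.999  # latent-scale magnitude


@dataclass(frozen=True)
class PlantedCrossPair:
    """A miRNA:gene coupling; mode 'all' plants the correlation across all
    samples, otherwise a rewiring class is planted as for PlantedEdge.
    ``signal_sd`` overrides the spec-wide latent amplitude (cross-layer
    selection at |r| > 0.85 tolerates a gentler, more realistic swing than
    the 0.99 rewiring threshold does)."""

    mirna_id: str
    gene_id: str
    r_target: float = -0.95
    mode: str = "all"  # 'all' or a RewireClass name
    signal_sd: float | None = None


@dataclass(frozen=True)
class PlantedDEGene:
    gene_id: str
    log2_fc: float
    group: str = _FOCAL  # group whose mean is shifted


@dataclass
class SimulationSpec:
    n_genes: int = 2000
    n_mirna: int = 290
    group_sizes: tuple[int, int, int] = (6, 6, 5)  # AI_PREG, NB_PREG, NON_PREG
    n_years: int = 1
    baseline_log_mean: float = np.log(1200.0)
    baseline_log_sd: float = 1.0
    mirna_log_mean: float = np.log(1200.0)
    mirna_log_sd: float = 1.0
    dispersion: float = 0.2
    # planted-edge features: tight dispersion and a small share of the
    # library so count noise and library-size fluctuation (a common-mode
    # term that CPM injects into every pair) barely attenuate the latent r
    planted_mean: float = 1000.0
    planted_dispersion: float = 5e-4
    signal_sd: float = 1.2  # latent signal SD on the natural-log scale
    # planted DE genes: moderate abundance, tight dispersion, so effects
    # near the detection limit of n = 5-6 survive leave-one-out rounds
    de_mean: float = 500.0
    de_dispersion: float = 0.05
    year_log_sd: float = 0.2  # per-gene year-two shift SD (natural log)
    planted_edges: list[PlantedEdge] = field(default_factory=list)
    planted_cross: list[PlantedCrossPair] = field(default_factory=list)
    planted_de: list[PlantedDEGene] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.group_sizes) < 3:
            raise ValueError("each outcome group needs >= 3 samples")
        if self.n_years not in (1, 2):
            raise ValueError("n_years must be 1 or 2")
        att = self.attenuation()
        for e in list(self.planted_edges) + list(self.planted_cross):
            if not abs(e.r_target) < 1:
                raise ValueError(
                    f"target |r| must be < 1 (attainable count-scale bound ~ {att:.4f})"
                )

    def attenuation(self) -> float:
        """Expected count-scale attenuation of planted correlations."""
        s2 = self.signal_sd**2
        noise = self.planted_dispersion + 1.0 / self.planted_mean
        return s2 / (s2 + noise)


@dataclass
class SimulatedDataset:
    mrna: CountMatrix
    mirna: CountMatrix
    samples: SampleTable
    annotation: FeatureAnnotation
    truth: dict[str, pd.DataFrame]
    spec: SimulationSpec


def _standardize(v: np.ndarray) -> np.ndarray:
    v = v - v.mean()
    return v / np.sqrt((v**2).mean())


def _correlated_pair(rng: np.random.Generator, n: int, r: float) -> tuple[np.ndarray, np.ndarray]:
    """Two vectors of length n with empirical correlation exactly r."""
    u = _standardize(rng.standard_normal(n))
    e = rng.standard_normal(n)
    e = e - u * (e @ u) / (u @ u)
    e = _standardize(e)
    return u, r * u + np.sqrt(1 - r**2) * e


def _orthogonal_pair(rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
    return _correlated_pair(rng, n, 0.0)


def _edge_signals(
    rng: np.random.Generator,
    klass: str,
    r: float,
    group_cols: dict[str, np.ndarray],
    n_total: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Latent (unit-scale) signal vectors for one planted edge."""
    a = np.zeros(n_total)
    b = np.zeros(n_total)
    r = abs(r)

    def plant(cols: np.ndarray, rr: float) -> None:
        u, v = _correlated_pair(rng, len(cols), rr)
        a[cols], b[cols] = u, v

    def absent(cols: np.ndarray) -> None:
        u, v = _orthogonal_pair(rng, len(cols))
        a[cols], b[cols] = u, v

    if klass in ("GAINED_POSITIVE", "GAINED_NEGATIVE"):
        plant(group_cols[_FOCAL], r if klass == "GAINED_POSITIVE" else -r)
        for g in _REFS:
            absent(group_cols[g])
    elif klass in ("LOST_POSITIVE", "LOST_NEGATIVE"):
        absent(group_cols[_FOCAL])
        for g in _REFS:
            plant(group_cols[g], r if klass == "LOST_POSITIVE" else -r)
    elif klass == "INVERTED":
        # sign flip large enough that |r_focal - r_ref| > 1.95
        plant(group_cols[_FOCAL], min(r, 0.999))
        for g in _REFS:
            plant(group_cols[g], -min(r, 0.999))
    else:
        raise ValueError(f"unknown rewiring class '{klass}'")
    return a, b


def simulate_dataset(spec: SimulationSpec) -> SimulatedDataset:
    """Draw one dataset from the spec; fully determined by (spec, seed)."""
    rng = np.random.default_rng(spec.seed)
    gene_ids = np.array([f"g{i:05d}" for i in range(spec.n_genes)])
    mirna_ids = np.array([f"mir{i:04d}" for i in range(spec.n_mirna)])

    # --- samples ------------------------------------------------------
    rows = []
    for year in range(1, spec.n_years + 1):
        for g, size in zip((Outcome.AI_PREG, Outcome.NB_PREG, Outcome.NON_PREG), spec.group_sizes):
            for i in range(size):
                rows.append(
                    {"sample_id": f"y{year}_{g.value.lower()}_{i+1}", "outcome": g.value, "year": year}
                )
    sdf = pd.DataFrame(rows).set_index("sample_id")
    samples = SampleTable(sdf)
    n_total = len(sdf)
    outcomes = sdf["outcome"].to_numpy()
    years = sdf["year"].to_numpy()
    group_cols = {g.value: np.flatnonzero(outcomes == g.value) for g in Outcome}

    # --- baseline means and dispersions -------------------------------
    base_g = np.exp(rng.normal(spec.baseline_log_mean, spec.baseline_log_sd, spec.n_genes))
    base_m = np.exp(rng.normal(spec.mirna_log_mean, spec.mirna_log_sd, spec.n_mirna))
    disp_g = np.full(spec.n_genes, spec.dispersion)
    disp_m = np.full(spec.n_mirna, spec.dispersion)

    gene_pos = {g: i for i, g in enumerate(gene_ids)}
    mir_pos = {m: i for i, m in enumerate(mirna_ids)}

    log_mu_g = np.log(base_g)[:, None] + np.zeros((spec.n_genes, n_total))
    log_mu_m = np.log(base_m)[:, None] + np.zeros((spec.n_mirna, n_total))

    # --- year effects (year 2 shifted per gene; applied after planting,
    # planted-edge features exempt so their class stays well-defined on the
    # pooled within-group correlation) -----------------------------------
    shift_g = rng.normal(0.0, spec.year_log_sd, spec.n_genes) if spec.n_years == 2 else None
    shift_m = rng.normal(0.0, spec.year_log_sd, spec.n_mirna) if spec.n_years == 2 else None

    # --- planted DE ----------------------------------------------------
    de_rows = []
    for d in spec.planted_de:
        i = gene_pos[d.gene_id]
        log_mu_g[i] += np.log(spec.de_mean) - np.log(base_g[i])
        disp_g[i] = spec.de_dispersion
        cols = np.flatnonzero(outcomes == d.group)
        log_mu_g[i, cols] += d.log2_fc * np.log(2.0)
        de_rows.append({"gene_id": d.gene_id, "log2_fc": d.log2_fc, "group": d.group})

    # --- planted rewired edges (per year, same class) -------------------
    att = spec.attenuation()
    edge_rows = []
    for e in spec.planted_edges:
        ia, ib = gene_pos[e.feature_a], gene_pos[e.feature_b]
        for i in (ia, ib):
            base = spec.planted_mean
            log_mu_g[i] += np.log(base) - np.log(base_g[i])
            disp_g[i] = spec.planted_dispersion
            if shift_g is not None:
                shift_g[i] = 0.0
        # exact empirical correlation over each pooled outcome group (the
        # scale on which within-group r is later measured)
        sa, sb = _edge_signals(rng, e.rewire_class, e.r_target, group_cols, n_total)
        log_mu_g[ia] += spec.signal_sd * sa
        log_mu_g[ib] += spec.signal_sd * sb
        edge_rows.append(
            {
                "feature_a": e.feature_a,
                "feature_b": e.feature_b,
                "rewire_class": e.rewire_class,
                "r_target": e.r_target,
                "expected_attenuation": att,
            }
        )

    # --- planted cross-layer couplings ---------------------------------
    cross_rows = []
    for c in spec.planted_cross:
        im, ig = mir_pos[c.mirna_id], gene_pos[c.gene_id]
        log_mu_m[im] += np.log(spec.planted_mean) - np.log(base_m[im])
        disp_m[im] = spec.planted_dispersion
        log_mu_g[ig] += np.log(spec.planted_mean) - np.log(base_g[ig])
        disp_g[ig] = spec.planted_dispersion
        amp = spec.signal_sd if c.signal_sd is None else c.signal_sd
        if c.mode == "all":
            u, v = _correlated_pair(rng, n_total, c.r_target)
            log_mu_m[im] += amp * u
            log_mu_g[ig] += amp * v
        else:
            sm, sg = _edge_signals(rng, c.mode, c.r_target, group_cols, n_total)
            log_mu_m[im] += amp * sm
            log_mu_g[ig] += amp * sg
            if shift_m is not None:
                shift_m[im] = 0.0
            if shift_g is not None:
                shift_g[ig] = 0.0
        cross_rows.append(
            {
                "mirna_id": c.mirna_id,
                "gene_id": c.gene_id,
                "mode": c.mode,
                "r_target": c.r_target,
                "expected_attenuation": att,
            }
        )

    if shift_g is not None:
        y2 = years == 2
        log_mu_g[:, y2] += shift_g[:, None]
        log_mu_m[:, y2] += shift_m[:, None]

    # --- draw counts ----------------------------------------------------
    def draw(log_mu: np.ndarray, phi: np.ndarray) -> np.ndarray:
        lam = np.exp(log_mu)
        out = np.empty_like(lam, dtype=np.int64)
        poisson_like = phi < 1e-12
        if poisson_like.any():
            out[poisson_like] = rng.poisson(lam[poisson_like])
        nb = ~poisson_like
        if nb.any():
            shape = 1.0 / phi[nb][:, None]
            mix = rng.gamma(shape, phi[nb][:, None] * lam[nb])
            out[nb] = rng.poisson(mix)
        return out

    counts_g = draw(log_mu_g, disp_g)
    counts_m = draw(log_mu_m, disp_m)

    mrna = CountMatrix(pd.DataFrame(counts_g, index=gene_ids, columns=sdf.index), Layer.MRNA)
    mirna = CountMatrix(pd.DataFrame(counts_m, index=mirna_ids, columns=sdf.index), Layer.MIRNA)

    # --- annotation -----------------------------------------------------
    ann = pd.DataFrame(
        {
            "feature_id": np.concatenate([gene_ids, mirna_ids]),
            "biotype": ["protein_coding"] * spec.n_genes + ["miRNA"] * spec.n_mirna,
            "length_bp": np.concatenate(
                [
                    np.exp(rng.normal(np.log(2000), 0.6, spec.n_genes)).astype(int) + 200,
                    rng.integers(60, 120, spec.n_mirna),
                ]
            ),
            "symbol": np.concatenate([gene_ids, mirna_ids]),
        }
    ).set_index("feature_id")

    truth = {
        "rewired_edges": pd.DataFrame(edge_rows),
        "cross_pairs": pd.DataFrame(cross_rows),
        "de_genes": pd.DataFrame(de_rows),
    }
    return SimulatedDataset(mrna, mirna, samples, FeatureAnnotation(ann), truth, spec)


def export_fixture(ds: SimulatedDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the dataset in the exact formats the loaders read, plus truth
    tables. Returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in (
        ("mrna_counts.tsv", ds.mrna.counts),
        ("mirna_counts.tsv", ds.mirna.counts),
    ):
        p = out / name
        df.to_csv(p, sep="\t", index_label="feature_id")
        paths[name] = p
    p = out / "samples.tsv"
    ds.samples.table.to_csv(p, sep="\t", index_label="sample_id")
    paths["samples.tsv"] = p
    p = out / "annotation.tsv"
    ds.annotation.table.to_csv(p, sep="\t", index_label="feature_id")
    paths["annotation.tsv"] = p
    for name, df in ds.truth.items():
        p = out / f"truth_{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths[p.name] = p
    return paths


# ---------------------------------------------------------------------------
# canned specs used across the test-bed


def null_spec(n_genes: int = 800, n_mirna: int = 60, seed: int = 0, **kw) -> SimulationSpec:
    """No planted structure: all outcome groups exchangeable."""
    return SimulationSpec(n_genes=n_genes, n_mirna=n_mirna, seed=seed, **kw)


def planted_rewiring_spec(
    n_edges: int = 50,
    n_genes: int = 400,
    classes: tuple[str, ...] = ("GAINED_POSITIVE", "GAINED_NEGATIVE"),
    r_target: float = 0.999,
    seed: int = 0,
    **kw,
) -> SimulationSpec:
    """Disjoint planted consensus-rewired gene pairs among noise genes."""
    if 2 * n_edges > n_genes:
        raise ValueError("need n_genes >= 2 * n_edges for disjoint pairs")
    edges = [
        PlantedEdge(
            f"g{2*i:05d}", f"g{2*i+1:05d}", classes[i % len(classes)], r_target
        )
        for i in range(n_edges)
    ]
    return SimulationSpec(n_genes=n_genes, n_mirna=10, planted_edges=edges, seed=seed, **kw)


def two_year_spec(
    n_genes: int = 500,
    n_mirna: int = 60,
    n_de: int = 60,
    n_edges: int = 10,
    n_cross: int = 10,
    de_log2fc: float = 2.6,
    seed: int = 0,
) -> SimulationSpec:
    """Two-cohort fixture exercising every pipeline stage: rewired edges,
    DE genes (non-pregnant shifted), an AI-vs-non-pregnant panel effect
    present in both years, and negative miRNA:mRNA couplings."""
    edges = [
        PlantedEdge(f"g{2*i:05d}", f"g{2*i+1:05d}",
                    ("GAINED_POSITIVE", "GAINED_NEGATIVE", "LOST_POSITIVE", "INVERTED")[i % 4],
                    0.999)
        for i in range(n_edges)
    ]
    first_free = 2 * n_edges
    de = [
        PlantedDEGene(f"g{first_free + i:05d}", de_log2fc * (1 if i % 2 == 0 else -1), _FOCAL)
        for i in range(n_de)
    ]
    # panel effect: AI-pregnant shifted, used by the prediction protocol
    panel_start = first_free + n_de
    de += [
        PlantedDEGene(f"g{panel_start + i:05d}", de_log2fc * (1 if i % 2 == 0 else -1),
                      Outcome.AI_PREG.value)
        for i in range(n_de)
    ]
    cross = [
        PlantedCrossPair(f"mir{i:04d}", f"g{panel_start + n_de + i:05d}", -0.95, "all", 0.6)
        for i in range(n_cross)
    ]
    return SimulationSpec(
        n_genes=n_genes,
        n_mirna=n_mirna,
        n_years=2,
        planted_edges=edges,
        planted_de=de,
        planted_cross=cross,
        seed=seed,
    )
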