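"""Seeded synthetic cohorts: slides, expression, GI networks, labels.

Each synthetic patient carries a latent factor vector z.  Slide tiles are
procedural textures — a fixed high-contrast carrier grating (so the tissue
filter always retains them) superimposed with one sinusoidal grating per
latent factor whose amplitude is linear in the factor value, plus pixel
noise.  A blank border ring of background tiles exercises the
gradient-based tissue filter.  Driven-gene log2 expression is a linear map
of z mixed with Gaussian noise at a configurable per-gene signal-to-noise
variance ratio s (so the image-predictable correlation of a driven gene is
sqrt(s/(1+s)) by construction); null genes are independent noise.  Counts
are obtained by exponentiating log2 expression, scaling by a per-sample
library factor and Poisson sampling, so the expressed-gene filter and CPM
normalization are exercised realistically.

A truth record persists everything downstream checks need: latent factors,
loadings, the driven-gene list, the noiseless expression matrix and (once a
GI network is drawn) the true per-patient EMS.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cv import Dataset
from .ems import GINetwork, score_cohort
from .expr_prep import (
    CountMatrix,
    ExpressionMatrix,
    filter_expressed_genes,
    make_tranches,
    normalize_expression,
)
from .features import FeatureMatrix, extract_features
from .slide_tiler import SlideImage, process_slide

__all__ = [
    "SyntheticCohortSpec",
    "SyntheticCohort",
    "generate_cohort",
    "generate_gi_network",
    "generate_response",
    "cohort_to_dataset",
    "write_cohort",
]

_PATTERN_FREQS = [(8, 0), (0, 16), (12, 12), (6, 18), (20, 6)]  # (x period, y period) px


@dataclass(frozen=True)
class SyntheticCohortSpec:
    n_patients: int = 40
    slides_per_patient: int = 1
    slide_dims: tuple[int, int] = (512, 512)
    tile_edge: int = 128
    n_genes: int = 200
    n_driven_genes: int = 50
    n_latent_factors: int = 3
    signal_to_noise: float = 4.0
    response_slope: float = 4.0
    response_intercept: float = -2.0
    blank_border: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_driven_genes > self.n_genes:
            raise ValueError("n_driven_genes must not exceed n_genes")
        if min(self.n_patients, self.slides_per_patient, self.n_genes,
               self.n_latent_factors, self.tile_edge) < 1:
            raise ValueError("all counts must be positive")
        if self.n_latent_factors > len(_PATTERN_FREQS):
            raise ValueError(f"at most {len(_PATTERN_FREQS)} latent factors supported")
        if min(self.slide_dims) < self.tile_edge:
            raise ValueError("slide too small to tile")


@dataclass
class SyntheticCohort:
    spec: SyntheticCohortSpec
    slides: list[SlideImage]
    counts: CountMatrix
    truth: dict = field(default_factory=dict)

    @property
    def patients(self) -> list[str]:
        return sorted({s.patient_id for s in self.slides})

    @property
    def slide_patients(self) -> dict[str, str]:
        return {s.slide_id: s.patient_id for s in self.slides}


def _render_slide(z: np.ndarray, spec: SyntheticCohortSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = spec.slide_dims
    edge = spec.tile_edge
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    carrier = np.sin(2 * np.pi * xx / 4.0) * np.sin(2 * np.pi * yy / 4.0)
    n_rows, n_cols = h // edge, w // edge
    gray = np.full((h, w), 235.0) + rng.normal(0.0, 0.5, size=(h, w))
    for r in range(n_rows):
        for c in range(n_cols):
            border = r in (0, n_rows - 1) or c in (0, n_cols - 1)
            if spec.blank_border and border and n_rows > 2 and n_cols > 2:
                continue  # background tile: stays blank, filtered out
            sl = np.s_[r * edge : (r + 1) * edge, c * edge : (c + 1) * edge]
            tile = 130.0 + 25.0 * carrier[sl]
            for j in range(spec.n_latent_factors):
                px, py = _PATTERN_FREQS[j]
                phase_x = 2 * np.pi * xx[sl] / px if px else 0.0
                phase_y = 2 * np.pi * yy[sl] / py if py else 0.0
                pattern = np.sin(phase_x + phase_y)
                amp = 12.0 * (1.0 + 0.35 * z[j]) * (1.0 + 0.05 * rng.normal())
                tile = tile + amp * pattern
            gray[sl] = tile + rng.normal(0.0, 3.0, size=(edge, edge))
    rgb = np.stack(
        [gray * 0.95 + 25.0, gray * 0.72 + 28.0, gray * 0.88 + 24.0], axis=-1
    )
    return np.clip(np.rint(rgb), 0, 255).astype(np.uint8)


def generate_cohort(spec: SyntheticCohortSpec) -> SyntheticCohort:
    """Generate slides, counts and the truth record for one seeded cohort."""
    rng = np.random.default_rng(spec.seed)
    k = spec.n_latent_factors
    patients = [f"P{i:03d}" for i in range(spec.n_patients)]
    z = np.clip(rng.normal(size=(k, spec.n_patients)), -2.5, 2.5)

    slides: list[SlideImage] = []
    for i, p in enumerate(patients):
        for j in range(spec.slides_per_patient):
            slides.append(
                SlideImage(
                    slide_id=f"{p}-S{j}", patient_id=p,
                    pixels=_render_slide(z[:, i], spec, rng),
                    preparation="synthetic",
                )
            )

    genes = [f"G{g:04d}" for g in range(spec.n_genes)]
    driven = genes[: spec.n_driven_genes]
    loadings = np.zeros((spec.n_driven_genes, k))
    if spec.n_driven_genes:
        raw = rng.normal(size=(spec.n_driven_genes, k))
        loadings = raw / np.linalg.norm(raw, axis=1, keepdims=True)

    s = spec.signal_to_noise
    sig_w = np.sqrt(s / (1.0 + s))
    noise_w = np.sqrt(1.0 / (1.0 + s))
    scale = 1.5  # log2-units spread of a gene across patients
    base = np.concatenate([
        rng.uniform(8.0, 12.0, size=spec.n_driven_genes),   # driven: high counts
        rng.uniform(3.0, 12.0, size=spec.n_genes - spec.n_driven_genes),
    ])
    signal = loadings @ z  # driven genes x patients
    eps = rng.normal(size=(spec.n_genes, spec.n_patients))
    log2_expr = base[:, None] + scale * noise_w * eps
    log2_expr[: spec.n_driven_genes] = (
        base[: spec.n_driven_genes, None]
        + scale * (sig_w * signal + noise_w * eps[: spec.n_driven_genes])
    )
    noiseless = np.tile(base[:, None], (1, spec.n_patients)).astype(float)
    noiseless[: spec.n_driven_genes] += scale * sig_w * signal

    lib = np.power(2.0, rng.normal(0.0, 0.2, size=spec.n_patients))
    counts = rng.poisson(np.power(2.0, log2_expr) * lib[None, :])
    cm = CountMatrix(pd.DataFrame(counts, index=genes, columns=patients))

    truth = {
        "z": pd.DataFrame(z, index=[f"factor{j}" for j in range(k)], columns=patients),
        "loadings": pd.DataFrame(loadings, index=driven,
                                 columns=[f"factor{j}" for j in range(k)]),
        "driven_genes": list(driven),
        "noiseless_log2": pd.DataFrame(noiseless, index=genes, columns=patients),
        "signal_correlation": float(sig_w),
    }
    return SyntheticCohort(spec=spec, slides=slides, counts=cm, truth=truth)


def generate_gi_network(
    cohort: SyntheticCohort, n_sl: int = 10, n_sr: int = 5, seed: int = 0,
    drug: str = "synthetic-drug",
) -> GINetwork:
    """Draw SL/SR partners from the driven genes; store the true EMS.

    Partners are the driven genes whose latent loadings best align with a
    seeded random pathway direction, so the partner set responds coherently
    to the latent state (as the interaction partners of one drug target
    would) and the true EMS varies widely across patients.  The true EMS of
    each patient — computed on the noiseless expression via the same
    scoring code — is persisted in the cohort truth record.
    """
    driven = cohort.truth["driven_genes"]
    if n_sl + n_sr < 1:
        raise ValueError("need at least one partner")
    if n_sl + n_sr > len(driven):
        raise ValueError(
            f"requested {n_sl + n_sr} partners but only {len(driven)} driven genes exist"
        )
    rng = np.random.default_rng(seed)
    u = rng.normal(size=cohort.spec.n_latent_factors)
    u /= np.linalg.norm(u)
    proj = cohort.truth["loadings"].to_numpy() @ u
    order = np.argsort(-proj)
    picks = list(np.array(driven)[order][: n_sl + n_sr])
    network = GINetwork(
        drug=drug, targets=["TARGET1"],
        sl_partners=picks[:n_sl], sr_partners=picks[n_sl:],
        provenance="synthetic fixture",
    )
    results = score_cohort(cohort.truth["noiseless_log2"], network)
    cohort.truth["true_ems"] = pd.Series(
        {r.patient_id: r.ems for r in results}, name="true_ems"
    )
    cohort.truth["network"] = network
    return network


def generate_response(
    true_ems: pd.Series, slope: float = 4.0, intercept: float = -2.0, seed: int = 0
) -> pd.Series:
    """Binary response labels ~ Bernoulli(logistic(slope*EMS + intercept))."""
    rng = np.random.default_rng(seed)
    prob = 1.0 / (1.0 + np.exp(-(slope * true_ems.to_numpy(dtype=float) + intercept)))
    return pd.Series(rng.random(len(true_ems)) < prob, index=true_ems.index,
                     name="response").astype(int)


def cohort_to_dataset(
    cohort: SyntheticCohort,
    backend: str = "deterministic-texture",
    tranche_size: int = 4096,
    cpm_min: float = 1.0,
    frac_samples: float = 0.2,
    gradient_threshold: float = 15.0,
) -> Dataset:
    """Run the desk-scale front half of the pipeline on a synthetic cohort.

    Tiles and filters every slide (identity colour normalization — the
    synthetic stain is already uniform), extracts raw backend features,
    filters/normalizes the counts and builds tranches; returns the
    training-ready :class:`~slide2rx.cv.Dataset`.
    """
    feats, tile_slides = [], []
    for slide in cohort.slides:
        ts = process_slide(
            slide, tile_edge=cohort.spec.tile_edge, threshold=gradient_threshold,
            color_norm="identity",
        )
        fm = extract_features(ts, backend=backend)
        feats.append(fm.features)
        tile_slides.extend([slide.slide_id] * fm.features.shape[0])
    features = np.concatenate(feats, axis=0)
    keep = filter_expressed_genes(cohort.counts, cpm_min=cpm_min, frac_samples=frac_samples)
    expr = normalize_expression(cohort.counts)
    expr = ExpressionMatrix(expr.values.loc[keep], expr.normalization_tag)
    tranches = make_tranches(expr, tranche_size=tranche_size)
    return Dataset(
        features=FeatureMatrix(
            [f"t{i}" for i in range(features.shape[0])], features, backend_tag=backend
        ),
        tile_slides=tile_slides,
        slide_patients=cohort.slide_patients,
        expr=expr,
        tranches=tranches,
    )


def write_cohort(cohort: SyntheticCohort, outdir) -> None:
    """Persist a cohort as PNG slides + TSV/JSON files (CLI `simulate`)."""
    from PIL import Image

    out = Path(outdir)
    (out / "slides").mkdir(parents=True, exist_ok=True)
    rows = []
    for s in cohort.slides:
        path = out / "slides" / f"{s.slide_id}.png"
        Image.fromarray(s.pixels).save(path)
        rows.append({"slide_id": s.slide_id, "patient_id": s.patient_id, "path": str(path)})
    pd.DataFrame(rows).to_csv(out / "manifest.tsv", sep="\t", index=False)
    cohort.counts.to_tsv(out / "counts.tsv")
    cohort.truth["noiseless_log2"].to_csv(out / "truth_noiseless_log2.tsv", sep="\t")
    cohort.truth["z"].to_csv(out / "truth_latent_factors.tsv", sep="\t")
    if "network" in cohort.truth:
        cohort.truth["network"].to_json(out / "network.json")
    if "true_ems" in cohort.truth:
        cohort.truth["true_ems"].to_csv(out / "truth_ems.tsv", sep="\t")
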