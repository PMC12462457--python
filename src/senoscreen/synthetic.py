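"""Synthetic data generators with recorded ground truth.

Every input the analysis consumes can be generated here: two-channel
fluorescence fields (Gaussian-blob cells), 384-well screen plates with
planted senolytic kill effects and per-plate batch effects, negative-
binomial expression matrices with a planted shared up/down senescence
program on top of strong cell-line-specific baselines, and 4PL-shaped
dose-response tables.

All generators are pure functions of their configuration and an explicit
seed; the same seed reproduces bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .imaging import ImageField


class PackingError(ValueError):
    """Centroid density exceeds what the field can hold without overlap."""


class LayoutError(ValueError):
    """A plate layout violates its invariants (e.g. no DMSO wells)."""


# ---------------------------------------------------------------------------
# microscopy fields


@dataclass(frozen=True)
class IlluminationGradient:
    """Smooth multiplicative shading: linear ramp along one axis.

    ``ratio`` is the bright-edge / dim-edge intensity ratio (>= 1);
    ``axis`` 0 ramps down rows, 1 down columns.
    """

    ratio: float = 1.0
    axis: int = 1

    def profile(self, shape: tuple[int, int]) -> np.ndarray:
        n = shape[self.axis]
        ramp = np.linspace(1.0, self.ratio, n)
        ramp /= ramp.mean()
        if self.axis == 0:
            return np.repeat(ramp[:, None], shape[1], axis=1)
        return np.repeat(ramp[None, :], shape[0], axis=0)


@dataclass(frozen=True)
class FieldTruth:
    """Ground truth for one synthetic field.

    Dead cells carry a nuclear blob but no cytoplasm blob (they are fixed
    cells whose cytoplasm stain is absent); live cells carry both.
    """

    live_centroids: tuple[tuple[float, float], ...]
    dead_centroids: tuple[tuple[float, float], ...] = ()
    shape: tuple[int, int] = (512, 512)
    nucleus_radius_px: float = 6.0
    cytoplasm_radius_px: float = 11.0
    background_level: float = 100.0
    nucleus_amplitude: float = 3000.0
    cytoplasm_amplitude: float = 1500.0
    read_noise_sd: float = 10.0
    illumination: IlluminationGradient | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nucleus_radius_px <= 0 or self.cytoplasm_radius_px <= 0:
            raise ValueError("blob radii must be positive")
        if self.cytoplasm_radius_px <= self.nucleus_radius_px:
            raise ValueError("cytoplasm radius must exceed nucleus radius")

    @property
    def live_count(self) -> int:
        return len(self.live_centroids)

    @property
    def dead_count(self) -> int:
        return len(self.dead_centroids)


def random_field_truth(
    n_live: int,
    n_dead: int = 0,
    shape: tuple[int, int] = (512, 512),
    min_separation: float = 24.0,
    seed: int = 0,
    max_tries: int = 20000,
    **kwargs,
) -> FieldTruth:
    """Place non-overlapping centroids by rejection sampling.

    Raises
    ------
    PackingError
        If the requested density cannot be placed within ``max_tries``
        proposals (the configured packing limit).
    """
    rng = np.random.default_rng(seed)
    margin = 3.5 * kwargs.get("cytoplasm_radius_px", 11.0) / 2.0 + 4.0
    placed: list[tuple[float, float]] = []
    tries = 0
    total = n_live + n_dead
    while len(placed) < total:
        tries += 1
        if tries > max_tries:
            raise PackingError(
                f"could not place {total} centroids at separation "
                f"{min_separation} in {shape} after {max_tries} proposals"
            )
        r = rng.uniform(margin, shape[0] - margin)
        c = rng.uniform(margin, shape[1] - margin)
        if all((r - pr) ** 2 + (c - pc) ** 2 >= min_separation**2 for pr, pc in placed):
            placed.append((r, c))
    return FieldTruth(
        live_centroids=tuple(placed[:n_live]),
        dead_centroids=tuple(placed[n_live:]),
        shape=shape,
        seed=seed,
        **kwargs,
    )


def _render_blobs(
    shape: tuple[int, int],
    centroids: tuple[tuple[float, float], ...],
    radius: float,
    amplitude: float,
) -> np.ndarray:
    """Sum of isotropic Gaussian profiles (sigma = radius/2, cut at 3 sigma)."""
    img = np.zeros(shape, dtype=float)
    sigma = radius / 2.0
    cut = 3.0 * sigma
    for r0, c0 in centroids:
        r_lo = max(0, int(np.floor(r0 - cut)))
        r_hi = min(shape[0], int(np.ceil(r0 + cut)) + 1)
        c_lo = max(0, int(np.floor(c0 - cut)))
        c_hi = min(shape[1], int(np.ceil(c0 + cut)) + 1)
        rr, cc = np.mgrid[r_lo:r_hi, c_lo:c_hi]
        d2 = (rr - r0) ** 2 + (cc - c0) ** 2
        blob = amplitude * np.exp(-d2 / (2.0 * sigma**2))
        blob[d2 > cut**2] = 0.0
        img[r_lo:r_hi, c_lo:c_hi] += blob
    return img


def gen_field(truth: FieldTruth) -> ImageField:
    """Render the two channels for one field.

    Channel 1 (nuclei) holds one blob per live + dead centroid; channel 2
    (cytoplasm) one blob per live centroid only.  Signal receives Poisson
    shot noise, then Gaussian read noise; an optional smooth multiplicative
    illumination gradient is applied to both channels before noise.
    """
    rng = np.random.default_rng(truth.seed)
    nuc = truth.background_level + _render_blobs(
        truth.shape,
        truth.live_centroids + truth.dead_centroids,
        truth.nucleus_radius_px,
        truth.nucleus_amplitude,
    )
    cyto = truth.background_level + _render_blobs(
        truth.shape,
        truth.live_centroids,
        truth.cytoplasm_radius_px,
        truth.cytoplasm_amplitude,
    )
    if truth.illumination is not None:
        profile = truth.illumination.profile(truth.shape)
        nuc *= profile
        cyto *= profile
    out = []
    for clean in (nuc, cyto):
        noisy = rng.poisson(clean).astype(float)
        noisy += rng.normal(0.0, truth.read_noise_sd, truth.shape)
        out.append(np.clip(np.round(noisy), 0, 65535).astype(np.uint16))
    return ImageField(nuclei_channel=out[0], cytoplasm_channel=out[1])


# ---------------------------------------------------------------------------
# screen plates

PLATE_ROWS = "ABCDEFGHIJKLMNOP"


def well_name(row: int, col: int) -> str:
    return f"{PLATE_ROWS[row]}{col + 1:02d}"


@dataclass
class ScreenTruth:
    """Planted effects behind a synthetic screen.

    ``kill_fraction`` maps (compound_id, concentration, condition) to the
    fraction of cells removed; ``plate_effect`` multiplies every count on a
    plate (the batch effect that per-plate DMSO normalization removes);
    well-to-well noise is lognormal with coefficient of variation
    ``well_noise_cv``.
    """

    kill_fraction: dict[tuple[str, float, str], float]
    plate_effect: dict[str, float]
    well_noise_cv: float = 0.15
    baseline_count: float = 5000.0
    seed: int = 0

    def __post_init__(self) -> None:
        for key, k in self.kill_fraction.items():
            if not 0.0 <= k <= 1.0:
                raise ValueError(f"kill_fraction out of [0,1] for {key}")
        for plate, e in self.plate_effect.items():
            if e <= 0:
                raise ValueError(f"plate_effect must be positive for {plate}")


def design_screen_layout(
    compound_ids: list[str],
    concentrations: tuple[float, ...] = (1.0, 5.0),
    conditions: tuple[str, ...] = ("CP", "CX"),
    n_replicates: int = 2,
    n_dmso: int = 16,
    n_positive: int = 16,
    rows: int = 16,
    cols: int = 24,
) -> pd.DataFrame:
    """Lay out a multi-plate 384-well screen.

    The last two columns of every plate hold DMSO vehicle and positive-
    control wells; the remaining wells carry one compound x concentration
    each.  Enough plates are created per condition x replicate to fit all
    compound/concentration pairs.  Returns a plate map with columns
    plate_id, well_id, role, compound_id, concentration_uM, condition,
    replicate.
    """
    sample_wells_per_plate = rows * cols - n_dmso - n_positive
    pairs = [(c, conc) for c in compound_ids for conc in concentrations]
    records = []
    for cond in conditions:
        for rep in range(1, n_replicates + 1):
            for start in range(0, len(pairs), sample_wells_per_plate):
                chunk = pairs[start:start + sample_wells_per_plate]
                plate_id = f"{cond}_r{rep}_p{start // sample_wells_per_plate + 1:02d}"
                # sample wells fill columns 1..cols-2 row-major
                positions = [
                    (r, c) for r in range(rows) for c in range(cols - 2)
                ]
                for (comp, conc), (r, c) in zip(chunk, positions):
                    records.append((plate_id, well_name(r, c), "sample",
                                    comp, conc, cond, rep))
                for i in range(n_dmso):
                    records.append((plate_id, well_name(i % rows, cols - 2),
                                    "dmso", "DMSO", 0.0, cond, rep))
                for i in range(n_positive):
                    records.append((plate_id, well_name(i % rows, cols - 1),
                                    "positive_control", "ABT-263", 10.0, cond, rep))
    df = pd.DataFrame(
        records,
        columns=["plate_id", "well_id", "role", "compound_id",
                 "concentration_uM", "condition", "replicate"],
    )
    return df


def make_screen_truth(
    platemap: pd.DataFrame,
    senolytic_ids: list[str] | None = None,
    senolytic_kill: float = 0.95,
    positive_control_kill: float = 0.85,
    background_kill: float = 0.0,
    plate_effect_range: tuple[float, float] = (0.5, 2.0),
    well_noise_cv: float = 0.15,
    baseline_count: float = 5000.0,
    seed: int = 0,
) -> ScreenTruth:
    """Plant senolytics (kill >= ``senolytic_kill`` in every condition and
    concentration) on an otherwise inert compound background."""
    rng = np.random.default_rng(seed)
    senolytics = set(senolytic_ids or [])
    kill: dict[tuple[str, float, str], float] = {}
    samples = platemap[platemap.role == "sample"]
    for comp, conc, cond in samples[
        ["compound_id", "concentration_uM", "condition"]
    ].drop_duplicates().itertuples(index=False):
        if comp in senolytics:
            k = senolytic_kill + rng.uniform(0.0, 1.0 - senolytic_kill)
        else:
            k = background_kill
        kill[(comp, conc, cond)] = k
    for comp, conc, cond in platemap.loc[
        platemap.role == "positive_control",
        ["compound_id", "concentration_uM", "condition"],
    ].drop_duplicates().itertuples(index=False):
        kill[(comp, conc, cond)] = positive_control_kill
    plates = platemap.plate_id.unique()
    effects = dict(zip(plates, rng.uniform(*plate_effect_range, len(plates))))
    return ScreenTruth(kill, effects, well_noise_cv, baseline_count, seed)


def gen_screen_plates(platemap: pd.DataFrame, truth: ScreenTruth) -> pd.DataFrame:
    """Simulate per-well raw viable-cell counts for a laid-out screen.

    count ~ round(baseline * plate_effect * (1 - kill) * lognormal(cv)).

    Raises
    ------
    LayoutError
        If any plate lacks DMSO wells or a well is assigned twice.
    """
    if platemap.duplicated(["plate_id", "well_id"]).any():
        raise LayoutError("duplicate (plate, well) assignment")
    for plate, grp in platemap.groupby("plate_id"):
        if not (grp.role == "dmso").any():
            raise LayoutError(f"plate {plate} has no DMSO wells")
    rng = np.random.default_rng(truth.seed)
    sigma = np.sqrt(np.log1p(truth.well_noise_cv**2))
    kills = np.array([
        0.0 if role == "dmso"
        else truth.kill_fraction.get((comp, conc, cond), 0.0)
        for role, comp, conc, cond in platemap[
            ["role", "compound_id", "concentration_uM", "condition"]
        ].itertuples(index=False)
    ])
    effects = platemap.plate_id.map(truth.plate_effect).to_numpy(dtype=float)
    noise = rng.lognormal(0.0, sigma, len(platemap)) if sigma > 0 else 1.0
    counts = np.round(truth.baseline_count * effects * (1.0 - kills) * noise)
    out = platemap[["plate_id", "well_id"]].copy()
    out["count"] = counts.astype(int)
    return out


# ---------------------------------------------------------------------------
# expression matrices


@dataclass
class ExpressionTruth:
    """Planted structure of a synthetic multi-cell-line expression study.

    A shared senescence program (``planted_up`` / ``planted_down`` genes,
    effect sizes ``lfc_up`` / ``lfc_down`` log2 units) is superimposed on
    strong cell-line-specific baselines; a fraction of non-planted genes
    additionally respond to treatment in a single cell line only, so that
    only the shared program survives the cross-line intersection.
    """

    planted_up: tuple[str, ...]
    planted_down: tuple[str, ...]
    n_genes: int = 2000
    n_celllines: int = 5
    drugs: tuple[str, ...] = ("cisplatin", "CX-5461")
    n_replicates: int = 5
    lfc_up: float = 4.0
    lfc_down: float = -4.0
    dispersion: float = 0.05
    libsize_range: tuple[float, float] = (4e6, 6e6)
    baseline_log_mean: float = 4.0   # ln scale, mean expression exp(4) ~ 55 counts/1e6... scaled by libsize
    baseline_log_sd: float = 1.0
    cellline_baseline_sd: float = 0.5
    frac_private_response: float = 0.05
    private_lfc_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if set(self.planted_up) & set(self.planted_down):
            raise ValueError("planted up/down gene sets overlap")
        if self.lfc_up < 0 or self.lfc_down > 0:
            # zero on both is the null design (no planted differential signal)
            raise ValueError("lfc_up must be >= 0 and lfc_down <= 0")
        if self.n_genes <= len(self.planted_up) + len(self.planted_down):
            raise ValueError("n_genes must exceed the planted program size")
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates per group")

    @property
    def cell_lines(self) -> list[str]:
        return [f"LINE{i + 1}" for i in range(self.n_celllines)]


def gen_expression(truth: ExpressionTruth) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate negative-binomial count matrices for every contrast.

    Returns ``(counts, samples)``: genes x samples counts and a sample
    sheet with columns sample_id, cell_line, drug, group
    (control/treated).  Treated groups shift the planted genes by
    lfc_up/lfc_down in every cell line; private (single-line) treatment
    responses are added to a random subset of non-planted genes.
    """
    rng = np.random.default_rng(truth.seed)
    genes = [f"G{i + 1:05d}" for i in range(truth.n_genes)]
    planted = list(truth.planted_up) + list(truth.planted_down)
    # planted genes take over the first slots' baselines; keep their names
    gene_names = planted + genes[len(planted):]
    base = rng.normal(truth.baseline_log_mean, truth.baseline_log_sd, truth.n_genes)
    up_idx = np.arange(len(truth.planted_up))
    down_idx = np.arange(len(truth.planted_up), len(planted))
    # the planted program models robustly expressed senescence genes: floor
    # its baseline one ln-unit above the gene average so the down-shifted
    # treated groups stay out of the shot-noise regime
    base[:len(planted)] = np.maximum(
        base[:len(planted)], truth.baseline_log_mean + 1.0
    )

    ln2 = np.log(2.0)
    r = 1.0 / truth.dispersion
    columns: dict[str, np.ndarray] = {}
    rows = []
    for li, line in enumerate(truth.cell_lines):
        line_shift = rng.normal(0.0, truth.cellline_baseline_sd, truth.n_genes)
        for drug in truth.drugs:
            # private treatment response in this line+drug only
            private = np.zeros(truth.n_genes)
            n_priv = int(truth.frac_private_response * truth.n_genes)
            priv_idx = len(planted) + rng.choice(
                truth.n_genes - len(planted), n_priv, replace=False
            )
            private[priv_idx] = rng.normal(0.0, truth.private_lfc_sd, n_priv)
            for group in ("control", "treated"):
                log_mu = base + line_shift
                if group == "treated":
                    shift = np.zeros(truth.n_genes)
                    shift[up_idx] = truth.lfc_up
                    shift[down_idx] = truth.lfc_down
                    log_mu = log_mu + (shift + private) * ln2
                rel = np.exp(log_mu)
                rel /= rel.sum()
                for rep in range(1, truth.n_replicates + 1):
                    lib = rng.uniform(*truth.libsize_range)
                    mu = rel * lib
                    p = r / (r + mu)
                    sample = f"{line}_{drug}_{group}_{rep}"
                    columns[sample] = rng.negative_binomial(r, p)
                    rows.append((sample, line, drug, group))
    counts = pd.DataFrame(columns, index=gene_names)
    counts.index.name = "gene_id"
    samples = pd.DataFrame(rows, columns=["sample_id", "cell_line", "drug", "group"])
    return counts, samples


# ---------------------------------------------------------------------------
# dose-response


def gen_dose_response(
    params,
    doses: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Sample viability responses from a 4PL curve plus Gaussian noise.

    ``params`` is a :class:`senoscreen.doseresponse.FourPL`.  Doses must be
    strictly positive and increasing.
    """
    from .doseresponse import four_pl

    doses = np.asarray(doses, dtype=float)
    if np.any(doses <= 0):
        raise ValueError("doses must be strictly positive")
    if np.any(np.diff(doses) <= 0):
        raise ValueError("doses must be strictly increasing")
    rng = np.random.default_rng(seed)
    resp = four_pl(doses, params.top, params.bottom, params.ic50, params.hill)
    if noise_sd > 0:
        resp = resp + rng.normal(0.0, noise_sd, len(doses))
    return pd.DataFrame({"dose_uM": doses, "response": resp})
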