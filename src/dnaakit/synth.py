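"""Synthetic data generators with ground truth, one per pipeline stage.

Each generator emulates the statistical structure its consumer assumes and
returns the generating truth alongside the data, so recovery can be tested
end to end without any external download:

* :func:`gen_genome` — a circular genome with concrete DnaA-box instances
  planted at positions drawn from a uniform/von Mises mixture around a
  chosen centre, for enrichment-recovery and null-calibration tests.
* :func:`gen_spt_dataset` — ThunderSTORM-dialect localisation tables from
  the two-state confined-diffusion simulator, laid out one active track per
  cell at a time so linking is unambiguous, plus per-cell areas.
* :func:`gen_fc_sample` — run-out DNA-content event lists with peaks at
  integer chromosome equivalents and a reference population at two.

Defaults mirror the study conditions: D_free = 2.7 um^2/s, sigma = 0.035 um,
10 ms frames, 0.1 ms sub-steps, track lengths 1-8 (mean 3); growth-regime
presets (slow/intermediate/fast) carry doubling times 187/62/31 min and
aspect ratios 3.43/4.14/4.3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .boxdensity import (DEFAULT_MOTIFS, CircularGenome, expand_motif,
                         reverse_complement)
from .cellcycle import ASPECT_RATIOS, DOUBLING_TIMES_MIN
from .mcdda import CellShape, TwoStateModel, simulate

#: Median projected cell area per growth regime (um^2), used by the
#: localisation generator's area draws.
MEDIAN_AREAS = {"slow": 1.5, "intermediate": 2.0, "fast": 2.5}


# ---------------------------------------------------------------------------
# Genomes
# ---------------------------------------------------------------------------

@dataclass
class GenomeSpec:
    length: int = 100_000
    gc: float = 0.5
    n_boxes: int = 100
    center_cs: float = 0.0  # planted enrichment centre, centisomes
    kappa_plant: float = 50.0  # von Mises concentration of planted positions
    uniform_fraction: float = 0.0  # fraction of boxes placed uniformly
    strand_skew: float = 0.5  # probability of the forward strand
    ori_position: int = 0
    ter_fraction: float = 0.5  # terminus at this fraction of L past ori
    motifs: tuple[str, ...] = DEFAULT_MOTIFS


def gen_genome(spec: GenomeSpec | None = None, seed: int = 0,
               **overrides) -> tuple[CircularGenome, pd.DataFrame]:
    """Generate a circular genome with planted DnaA-box instances.

    Background bases are i.i.d. at the requested GC; ``n_boxes`` concrete
    motif instances (drawn uniformly from the expansions of a random query
    motif) are written at positions sampled from
    uniform_fraction * Uniform + (1 - uniform_fraction) * vonMises(center, kappa),
    on strands drawn per ``strand_skew``.  Overlapping plants are redrawn.
    Returns the genome and the planted-truth table; accidental background
    matches can exist (and are realistic), so recovery tests should compare
    against a scan, not only against this table.
    """
    spec = spec or GenomeSpec()
    if overrides:
        spec = GenomeSpec(**{**spec.__dict__, **overrides})
    if spec.length < 10_000:
        raise ValueError("genome length must be >= 10 kb")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - spec.gc) / 2, spec.gc / 2, spec.gc / 2, (1 - spec.gc) / 2])
    seq = rng.choice(np.array(list("ACGT")), size=spec.length, p=p)

    expansions = {m: sorted(expand_motif(m)) for m in spec.motifs}
    motif_len = max(len(m) for m in spec.motifs)
    if spec.n_boxes * motif_len * 4 > spec.length:
        raise ValueError("box density too high to place without overlap")

    occupied = np.zeros(spec.length, dtype=bool)
    rows = []
    for _ in range(spec.n_boxes):
        for _attempt in range(1000):
            if rng.random() < spec.uniform_fraction or spec.kappa_plant == 0:
                cs = rng.uniform(0.0, 100.0)
            else:
                theta = rng.vonmises(spec.center_cs * 2 * np.pi / 100.0,
                                     spec.kappa_plant)
                cs = (theta % (2 * np.pi)) * 100.0 / (2 * np.pi)
            pos = int(spec.ori_position + round(cs / 100.0 * spec.length)) \
                % spec.length
            span = (np.arange(pos, pos + motif_len)) % spec.length
            if not occupied[span].any():
                break
        else:
            raise ValueError("box density too high to place without overlap")
        motif = spec.motifs[rng.integers(len(spec.motifs))]
        inst = expansions[motif][rng.integers(len(expansions[motif]))]
        strand = "+" if rng.random() < spec.strand_skew else "-"
        written = inst if strand == "+" else reverse_complement(inst)
        for k, ch in enumerate(written):
            seq[(pos + k) % spec.length] = ch
        occupied[(np.arange(pos, pos + len(written))) % spec.length] = True
        rows.append((pos, strand, motif, inst))

    genome = CircularGenome(
        id=f"synthetic_{seed}", sequence="".join(seq),
        ori_position=spec.ori_position,
        ter_position=(spec.ori_position
                      + int(spec.ter_fraction * spec.length)) % spec.length,
    )
    truth = pd.DataFrame(rows, columns=["position", "strand", "motif", "instance"])
    truth["centisome"] = genome.to_centisomes(truth["position"].to_numpy())
    truth = truth.sort_values("position").reset_index(drop=True)
    truth.attrs["seed"] = seed
    return genome, truth


# ---------------------------------------------------------------------------
# Single-particle tracking datasets
# ---------------------------------------------------------------------------

@dataclass
class SptSpec:
    model: TwoStateModel = field(
        default_factory=lambda: TwoStateModel(k_fb=186.0, k_bf=62.0))
    shape: CellShape = field(default_factory=CellShape)
    n_cells: int = 20
    mean_tracks_per_cell: float = 30.0
    regime: str = "slow"
    cell_pitch_um: float = 5.0  # spacing of the synthetic cell grid
    cell_box_um: float = 4.0  # side of each square cell region
    first_frame: int = 500
    frame_gap: int = 2  # empty frames between consecutive tracks in a cell
    start_state: int | None = None  # force the initial state (0 free, 1 bound)


def gen_spt_dataset(spec: SptSpec | None = None, seed: int = 0
                    ) -> tuple[pd.DataFrame, list, dict[int, float], dict]:
    """Generate a localisation table, cell regions, areas and truth.

    Tracks are simulated with the two-state forward simulator, assigned to
    cells on a square grid, and written out frame-by-frame with one active
    track per cell at a time (consecutive tracks separated by empty frames),
    so nearest-neighbour linking is unambiguous.  Returns
    ``(localisations, cell_polygons, areas, truth)`` where the localisation
    table uses the ThunderSTORM dialect (``frame``, ``x [nm]``, ``y [nm]``)
    and truth carries the generating rates and per-track assignments.
    """
    from shapely.geometry import box

    spec = spec or SptSpec()
    rng = np.random.default_rng(seed)
    n_tracks_per_cell = rng.poisson(spec.mean_tracks_per_cell, size=spec.n_cells)
    n_tracks_per_cell = np.maximum(n_tracks_per_cell, 1)
    total = int(n_tracks_per_cell.sum())
    sim = simulate(spec.model, spec.shape, n_particles=total,
                   seed=int(rng.integers(2**31)), start_state=spec.start_state)

    n_side = int(np.ceil(np.sqrt(spec.n_cells)))
    pitch, half_box = spec.cell_pitch_um, spec.cell_box_um / 2.0
    centers = {}
    polygons = []
    for c in range(spec.n_cells):
        cx = (c % n_side) * pitch + pitch / 2.0
        cy = (c // n_side) * pitch + pitch / 2.0
        centers[c + 1] = (cx, cy)
        polygons.append(box(cx - half_box, cy - half_box,
                            cx + half_box, cy + half_box))

    regime_area = MEDIAN_AREAS.get(spec.regime, 1.5)
    areas = {cid: float(a) for cid, a in zip(
        centers, np.maximum(rng.normal(regime_area, 0.2 * regime_area,
                                       spec.n_cells), 0.3))}

    rows = []
    truth_tracks = []
    tid = 0
    for cid, n_tr in zip(centers, n_tracks_per_cell):
        cx, cy = centers[cid]
        frame = spec.first_frame
        for _ in range(n_tr):
            n = int(sim.n_locs[tid])
            xy = sim.observed_xy[tid, :n]
            for j in range(n):
                rows.append((frame + j, (cx + xy[j, 0]) * 1000.0,
                             (cy + xy[j, 1]) * 1000.0))
            truth_tracks.append((tid, cid, frame, n))
            frame += n + spec.frame_gap
            tid += 1
    locs = pd.DataFrame(rows, columns=["frame", "x [nm]", "y [nm]"])
    locs = locs.sort_values(["frame"], kind="stable").reset_index(drop=True)
    truth = {
        "k_fb": spec.model.k_fb,
        "k_bf": spec.model.k_bf,
        "p_bound": (spec.model.bound_fraction()
                    if spec.model.k_fb + spec.model.k_bf > 0 else None),
        "areas": areas,
        "tracks": pd.DataFrame(truth_tracks,
                               columns=["particle", "cell_id",
                                        "first_frame", "n_locs"]),
        "seed": seed,
        "sim": sim,
    }
    return locs, polygons, areas, truth


# ---------------------------------------------------------------------------
# Flow-cytometry samples
# ---------------------------------------------------------------------------

@dataclass
class FcSpec:
    weights: dict[int, float] = field(default_factory=lambda: {1: 0.7, 2: 0.3})
    # intensity per chromosome equivalent, chosen so integer peaks are far
    # apart relative to the 500 A.U. counting window while the peak sd
    # (cv * n * unit) stays well inside it
    unit_au: float = 2_000.0
    cv: float = 0.03  # lognormal coefficient of variation
    n_events: int = 10_000
    n_reference: int = 5_000


def gen_fc_sample(spec: FcSpec | None = None, seed: int = 0
                  ) -> tuple[np.ndarray, np.ndarray, dict]:
    """Generate run-out DNA-content events plus a 2N reference population.

    Each experimental cell draws an origin number from ``weights``; its
    intensity is n * unit_au * lognormal(cv).  The reference population sits
    at two chromosome equivalents.  Returns (events, reference_events, truth).
    """
    spec = spec or FcSpec()
    w = dict(spec.weights)
    tot = sum(w.values())
    if abs(tot - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    rng = np.random.default_rng(seed)
    ns = np.array(sorted(w))
    probs = np.array([w[n] for n in ns])
    draws = rng.choice(ns, size=spec.n_events, p=probs)

    def noisy(base, size):
        if spec.cv == 0:
            return base * np.ones(size) if np.isscalar(base) else base
        sigma = np.sqrt(np.log1p(spec.cv**2))
        return base * np.exp(rng.normal(-sigma**2 / 2, sigma, size))

    events = noisy(draws * spec.unit_au, spec.n_events)
    reference = noisy(2.0 * spec.unit_au, spec.n_reference)
    truth = {
        "average_origins": float((ns * probs).sum()),
        "asynchrony_index": float(probs[[(n & (n - 1)) != 0 for n in ns]].sum()),
        "fraction_one_origin": float(w.get(1, 0.0)),
        "reference_2n_peak": 2.0 * spec.unit_au,
        "seed": seed,
    }
    return events, reference, truth


def regime_presets() -> pd.DataFrame:
    """Growth-regime presets: doubling time and aspect ratio."""
    return pd.DataFrame({
        "regime": list(ASPECT_RATIOS),
        "doubling_time_min": [DOUBLING_TIMES_MIN[r] for r in ASPECT_RATIOS],
        "aspect_ratio": [ASPECT_RATIOS[r] for r in ASPECT_RATIOS],
        "median_area_um2": [MEDIAN_AREAS[r] for r in ASPECT_RATIOS],
    })
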