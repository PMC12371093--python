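"""DnaA-box density analysis on circular chromosomes.

The replication initiator DnaA binds a degenerate 9-bp motif (the DnaA box)
scattered in the hundreds over the *E. coli* chromosome.  This module scans a
circular replicon for exact matches to IUPAC-degenerate box motifs on both
strands, maps them to centisome coordinates anchored at *oriC*, and tests
their positional enrichment against two null models:

* a **uniform null** — box positions redrawn uniformly on the circle, and
* a **motif-permutation null** — the motif strings themselves shuffled and the
  genome rescanned, which controls for compositional gradients (GC skew).

Both produce per-position percentile envelopes and one-sided enrichment
pseudo p-values by rank.  A circular von Mises kernel density, standardised
to Z-scores, summarises the box distribution and locates its density maxima.

The high-level entry point is :class:`BoxDensityModel`, whose :meth:`fit`
runs scan → windowed counts → null envelopes → significant regions → KDE and
returns a :class:`BoxDensityResults`.
"""

from __future__ import annotations

import itertools
import logging
import re
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import maximum_filter1d, minimum_filter1d
from scipy.special import i0e

logger = logging.getLogger(__name__)

DEFAULT_MOTIFS = ("TTWTNCACA", "HHMTHCWVH")

#: IUPAC nucleotide codes -> concrete bases they stand for.
IUPAC_CODES = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

#: Complement of each IUPAC code (complement of the base set).
IUPAC_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D", "N": "N",
}

_COMPLEMENT_TABLE = str.maketrans("ACGTN", "TGCAN")


class DegenerateProfileError(ValueError):
    """Raised when extremum calling is attempted on a constant profile."""


def reverse_complement(seq: str) -> str:
    """Reverse complement of a concrete A/C/G/T/N sequence."""
    return seq.translate(_COMPLEMENT_TABLE)[::-1]


def reverse_complement_iupac(motif: str) -> str:
    """Reverse complement of an IUPAC-degenerate motif string."""
    return "".join(IUPAC_COMPLEMENT[c] for c in reversed(motif.upper()))


@dataclass(frozen=True)
class CircularGenome:
    """A circular replicon with an origin (and optional terminus) anchor.

    Positions are 0-based offsets into ``sequence``; all positional
    arithmetic is modular, so ``position % len(sequence)`` always indexes a
    real base.  ``ori_position`` is the coordinate of the *oriC* start and is
    centisome 0 of every downstream positional analysis.
    """

    id: str
    sequence: str
    ori_position: int
    ter_position: int | None = None

    def __post_init__(self):
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise ValueError("genome sequence is empty")
        bad = set(seq) - set("ACGTN")
        if bad:
            raise ValueError(f"sequence contains non-ACGTN characters: {sorted(bad)}")
        if not 0 <= self.ori_position < len(seq):
            raise ValueError(
                f"ori_position {self.ori_position} outside [0, {len(seq)})"
            )
        if self.ter_position is not None and not 0 <= self.ter_position < len(seq):
            raise ValueError("ter_position outside genome")

    def __len__(self) -> int:
        return len(self.sequence)

    def to_centisomes(self, position: int | np.ndarray) -> float | np.ndarray:
        """Map a bp coordinate to centisomes from *oriC*, in [0, 100).

        The centisome increases in the direction of increasing sequence
        coordinate from *oriC*.
        """
        pos = np.asarray(position)
        if np.any(pos < 0) or np.any(pos >= len(self)):
            raise ValueError(f"position outside [0, {len(self)})")
        cs = ((pos - self.ori_position) % len(self)) / len(self) * 100.0
        return float(cs) if np.isscalar(position) else cs


def expand_motif(motif: str) -> set[str]:
    """Expand an IUPAC-degenerate motif into the set of concrete sequences.

    >>> sorted(expand_motif("AY"))
    ['AC', 'AT']
    """
    motif = motif.upper()
    if not motif:
        raise ValueError("empty motif")
    pools = []
    for ch in motif:
        if ch not in IUPAC_CODES:
            raise ValueError(f"unknown IUPAC code {ch!r} in motif {motif!r}")
        pools.append(IUPAC_CODES[ch])
    return {"".join(p) for p in itertools.product(*pools)}


def motif_regex(motif: str) -> re.Pattern:
    """Compile an IUPAC motif into an overlapping-match regex.

    Character classes never include N, so an N in the genome matches nothing.
    """
    motif = motif.upper()
    parts = []
    for ch in motif:
        if ch not in IUPAC_CODES:
            raise ValueError(f"unknown IUPAC code {ch!r} in motif {motif!r}")
        bases = IUPAC_CODES[ch]
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return re.compile("(?=" + "".join(parts) + ")")


@dataclass(frozen=True)
class BoxMatch:
    """One deduplicated motif-match site on the forward coordinate system.

    ``position`` is the leftmost base of the matched window regardless of
    strand; ``motifs_hit`` lists every query motif matching at this
    (position, strand).
    """

    position: int
    strand: str
    motifs_hit: tuple[str, ...]
    centisome: float


def scan_motifs(
    genome: CircularGenome,
    motifs: tuple[str, ...] | list[str] = DEFAULT_MOTIFS,
) -> list[BoxMatch]:
    """Find every exact degenerate-motif match on either strand.

    The scan is wrap-aware: the sequence is extended by ``len(motif) - 1``
    bases past the coordinate origin so matches spanning it are found once,
    at their position mod L.  A site matching several query motifs is
    reported once with all of them in ``motifs_hit``; a reverse-strand match
    is located by scanning the forward sequence with the reverse-complemented
    motif, so ``position`` stays the leftmost forward-coordinate base.
    """
    L = len(genome)
    motifs = tuple(m.upper() for m in motifs)
    if not motifs:
        raise ValueError("no motifs given")
    longest = max(len(m) for m in motifs)
    if L < longest:
        raise ValueError("genome shorter than the longest motif")

    hits: dict[tuple[int, str], set[str]] = {}
    for motif in motifs:
        ext = genome.sequence + genome.sequence[: len(motif) - 1]
        for strand, pattern in (
            ("+", motif_regex(motif)),
            ("-", motif_regex(reverse_complement_iupac(motif))),
        ):
            for m in pattern.finditer(ext):
                pos = m.start() % L
                hits.setdefault((pos, strand), set()).add(motif)

    matches = [
        BoxMatch(
            position=pos,
            strand=strand,
            motifs_hit=tuple(sorted(ms)),
            centisome=genome.to_centisomes(pos),
        )
        for (pos, strand), ms in hits.items()
    ]
    matches.sort(key=lambda b: (b.position, b.strand))
    return matches


# ---------------------------------------------------------------------------
# Windowed density and null models
# ---------------------------------------------------------------------------

@dataclass
class DensityProfile:
    """Boxes per sliding centisome window, one window per integer centisome.

    A match at centisome x belongs to the window centred at c iff the signed
    circular offset of x from c lies in [-w/2, w/2) (left edge closed), so
    every match falls in exactly ``window_cs`` windows at 1-cs steps.
    """

    window_cs: int
    counts: np.ndarray  # shape (100,), counts[c] for centers 0..99
    n_matches: int
    centers: np.ndarray = field(default_factory=lambda: np.arange(100))


def _window_counts_from_cs(cs: np.ndarray, window_cs: int) -> np.ndarray:
    """Window counts for an array of centisome positions (vectorised, exact).

    Window edges c +/- w/2 are half-integer multiples, so counting on a
    0.5-cs grid is exact.
    """
    if window_cs < 1 or window_cs > 100:
        raise ValueError("window_cs must be in 1..100")
    hist, _ = np.histogram(np.asarray(cs, dtype=float) % 100.0,
                           bins=200, range=(0.0, 100.0))
    ext = np.concatenate([hist, hist])
    sw = np.lib.stride_tricks.sliding_window_view(ext, 2 * window_cs).sum(axis=1)
    starts = (2 * np.arange(100) - window_cs) % 200
    return sw[starts]


def window_counts(
    matches: list[BoxMatch] | np.ndarray,
    window_cs: int,
    mask_cs: tuple[float, float] | None = None,
) -> DensityProfile:
    """Sliding-window box counts over the scaled (centisome) chromosome.

    Parameters
    ----------
    matches
        BoxMatch list, or directly an array of centisome positions.
    window_cs
        Window width in centisomes (the study used 2, 6 or 10).
    mask_cs
        Optional circular centisome interval ``(lo, hi)`` whose matches are
        removed before counting (e.g. to exclude *oriC* itself).
    """
    if isinstance(matches, np.ndarray):
        cs = matches.astype(float)
    else:
        cs = np.array([m.centisome for m in matches], dtype=float)
    if mask_cs is not None:
        lo, hi = mask_cs
        if lo <= hi:
            keep = ~((cs >= lo) & (cs <= hi))
        else:  # wraps through 0
            keep = ~((cs >= lo) | (cs <= hi))
        cs = cs[keep]
    counts = _window_counts_from_cs(cs, window_cs)
    return DensityProfile(window_cs=window_cs, counts=counts, n_matches=len(cs))


@dataclass
class NullEnvelope:
    """Per-centisome null percentile band and enrichment pseudo p-values.

    pseudo_p(c) = (1 + #{null replicates with count(c) >= observed(c)})
                  / (n_sims + 1), a one-sided rank estimator that can never
    return exactly zero.
    """

    lo: np.ndarray
    hi: np.ndarray
    pseudo_p: np.ndarray
    n_sims: int
    null_kind: str
    seed: int | None
    percentiles: tuple[float, float] = (5.0, 95.0)


def _envelope_from_sims(sim_counts: np.ndarray, observed: np.ndarray,
                        null_kind: str, seed: int | None,
                        percentiles=(5.0, 95.0)) -> NullEnvelope:
    lo, hi = np.percentile(sim_counts, percentiles, axis=0)
    n_sims = sim_counts.shape[0]
    exceed = (sim_counts >= observed[None, :]).sum(axis=0)
    pseudo_p = (1.0 + exceed) / (n_sims + 1.0)
    return NullEnvelope(lo=lo, hi=hi, pseudo_p=pseudo_p, n_sims=n_sims,
                        null_kind=null_kind, seed=seed, percentiles=percentiles)


def uniform_null(
    profile: DensityProfile,
    n_sims: int = 1000,
    seed: int | None = None,
    n_boxes: int | None = None,
) -> NullEnvelope:
    """Uniform-position null: redraw box positions uniformly on the circle.

    ``n_sims`` independent replicates of ``n_boxes`` positions uniform on
    [0, 100) are windowed exactly as the observed profile; the envelope is
    the per-centisome 5th/95th percentile band.
    """
    if n_sims < 2:
        raise ValueError("n_sims must be >= 2")
    n_boxes = profile.n_matches if n_boxes is None else n_boxes
    if n_boxes < 1:
        raise ValueError("n_boxes must be >= 1")
    rng = np.random.default_rng(seed)
    positions = rng.uniform(0.0, 100.0, size=(n_sims, n_boxes))
    # exact 0.5-cs binning, vectorised over replicates
    half_bins = np.floor(positions * 2.0).astype(np.int64)
    offsets = (np.arange(n_sims) * 200)[:, None]
    flat = np.bincount((half_bins + offsets).ravel(), minlength=n_sims * 200)
    hist = flat.reshape(n_sims, 200)
    ext = np.concatenate([hist, hist], axis=1)
    csum = np.concatenate(
        [np.zeros((n_sims, 1), dtype=np.int64), np.cumsum(ext, axis=1)], axis=1
    )
    starts = (2 * np.arange(100) - profile.window_cs) % 200
    sim_counts = csum[:, starts + 2 * profile.window_cs] - csum[:, starts]
    return _envelope_from_sims(sim_counts, profile.counts, "uniform", seed)


def shuffle_motif(motif: str, rng: np.random.Generator) -> str:
    """Random permutation of a motif's characters (IUPAC codes move as units)."""
    chars = list(motif.upper())
    return "".join(rng.permutation(chars))


def permuted_motif_null(
    genome: CircularGenome,
    motifs: tuple[str, ...] | list[str],
    profile: DensityProfile,
    n_perm: int = 1000,
    seed: int | None = None,
    mask_cs: tuple[float, float] | None = None,
) -> NullEnvelope:
    """Motif-permutation null: shuffle motif strings, rescan, rewindow.

    Each replicate shuffles the character order of every query motif
    (preserving its letter multiset, degenerate codes included), scans the
    genome for exact matches to the shuffled motifs and windows them exactly
    as the observed profile.  High observed counts that survive this null are
    not explained by the genome's compositional background.
    """
    if n_perm < 2:
        raise ValueError("n_perm must be >= 2")
    rng = np.random.default_rng(seed)
    sim_counts = np.empty((n_perm, 100), dtype=np.int64)
    for i in range(n_perm):
        shuffled = [shuffle_motif(m, rng) for m in motifs]
        perm_matches = scan_motifs(genome, shuffled)
        sim_counts[i] = window_counts(
            perm_matches, profile.window_cs, mask_cs=mask_cs
        ).counts
    return _envelope_from_sims(sim_counts, profile.counts, "permuted_motif", seed)


def significant_regions(
    envelope: NullEnvelope, alpha: float = 0.05
) -> list[tuple[int, int]]:
    """Maximal runs of consecutive centisomes with pseudo_p < alpha.

    Runs are merged circularly across the 99 -> 0 boundary; each interval is
    returned as an inclusive ``(start, end)`` pair of integer centisomes
    (start > end means the run wraps through 0).
    """
    sig = envelope.pseudo_p < alpha
    n = sig.size
    if not sig.any():
        return []
    if sig.all():
        return [(0, n - 1)]
    # rotate so index 0 is not significant, find runs, rotate back
    start0 = int(np.argmin(sig))  # first False
    rot = np.roll(sig, -start0)
    edges = np.flatnonzero(np.diff(rot.astype(int)))
    runs = []
    opens = None
    for e in edges:
        if rot[e + 1]:  # rising edge: run starts at e+1
            opens = e + 1
        else:  # falling edge: run ends at e
            runs.append((opens, e))
    if opens is not None and rot[-1]:
        runs.append((opens, n - 1))
    return [((a + start0) % n, (b + start0) % n) for a, b in runs]


# ---------------------------------------------------------------------------
# Circular kernel density
# ---------------------------------------------------------------------------

@dataclass
class KDEProfile:
    """Von Mises circular KDE of box positions, standardised to Z-scores.

    ``density`` integrates to 1 over the circle (in radians) before
    standardisation; ``zscore`` has grid mean 0 and sd 1 by construction.
    """

    grid_cs: np.ndarray
    zscore: np.ndarray
    density: np.ndarray
    kappa: float
    maxima: list["Extremum"] = field(default_factory=list)


@dataclass
class Extremum:
    position_cs: float
    zscore: float
    is_global: bool
    dist_from_ori_cs: float


def vonmises_zscore(
    matches: list[BoxMatch] | np.ndarray,
    kappa: float = 200.0,
    n_grid: int = 1000,
) -> KDEProfile:
    """Circular von Mises kernel density of match positions, as Z-scores.

    Each match at centisome x contributes a von Mises kernel of concentration
    ``kappa`` centred at angle 2*pi*x/100; the summed density is evaluated on
    a regular ``n_grid`` grid and standardised over the grid (mean 0, sd 1).
    kappa = 200 gives a kernel angular sd of ~1.1 centisomes.
    """
    if kappa <= 0:
        raise ValueError("kappa must be > 0")
    if isinstance(matches, np.ndarray):
        cs = matches.astype(float)
    else:
        cs = np.array([m.centisome for m in matches], dtype=float)
    if cs.size == 0:
        raise ValueError("need at least one match")
    theta_i = cs * (2 * np.pi / 100.0)
    grid_cs = np.arange(n_grid) * (100.0 / n_grid)
    theta_g = grid_cs * (2 * np.pi / 100.0)
    # exp(kappa*cos(d)) / (2*pi*I0(kappa)) computed via i0e for stability
    delta = theta_g[:, None] - theta_i[None, :]
    dens = np.exp(kappa * (np.cos(delta) - 1.0)).sum(axis=1)
    dens /= cs.size * 2 * np.pi * i0e(kappa)
    mu, sd = dens.mean(), dens.std()
    if sd <= 1e-12 * abs(mu):
        # numerically flat density: Z-scores are zero, not amplified noise
        z = np.zeros_like(dens)
    else:
        z = (dens - mu) / sd
    return KDEProfile(grid_cs=grid_cs, zscore=z, density=dens, kappa=kappa)


def find_extrema(kde: KDEProfile, neighborhood_cs: float = 5.0) -> list[Extremum]:
    """Local maxima of the Z-score curve on the circular grid.

    A grid point is a local maximum when it is >= every value within
    +/- ``neighborhood_cs`` (circular); plateau runs are collapsed to their
    first point.  The largest maximum is flagged global.  Raises
    :class:`DegenerateProfileError` on a constant profile.
    """
    z = kde.zscore
    n = z.size
    if np.ptp(z) == 0:
        raise DegenerateProfileError("constant density profile has no extrema")
    half = max(1, int(round(neighborhood_cs * n / 100.0)))
    size = 2 * half + 1
    filt = maximum_filter1d(z, size=size, mode="wrap")
    minf = minimum_filter1d(z, size=size, mode="wrap")
    # a maximum must top its neighbourhood AND the neighbourhood must vary:
    # numerically flat tails (underflowed density) are not extrema
    is_max = (z >= filt) & (filt > minf)
    # collapse circular plateau runs to a single representative
    idx = np.flatnonzero(is_max)
    keep = []
    visited = np.zeros(n, bool)
    for i in idx:
        if visited[i]:
            continue
        j = i
        while is_max[(j + 1) % n] and (j + 1 - i) < n:
            j += 1
            visited[j % n] = True
        keep.append(i)
    if not keep:
        raise DegenerateProfileError("profile locally constant everywhere")
    best = max(keep, key=lambda i: z[i])
    out = []
    for i in sorted(keep):
        pos = kde.grid_cs[i]
        dist = min(pos % 100.0, 100.0 - pos % 100.0)
        out.append(Extremum(position_cs=float(pos), zscore=float(z[i]),
                            is_global=(i == best), dist_from_ori_cs=float(dist)))
    kde.maxima = out
    return out


def strand_bias(matches: list[BoxMatch], genome: CircularGenome) -> dict:
    """Fraction of matches on the lagging-strand template, per replichore.

    The right replichore runs from *oriC* toward *ter* in increasing
    coordinates; there the fork moves with the sequence, so forward-strand
    matches sit on the lagging-strand template.  The convention reverses on
    the left replichore.
    """
    if genome.ter_position is None:
        raise ValueError("genome.ter_position is required for strand bias")
    L = len(genome)
    arc_right = (genome.ter_position - genome.ori_position) % L
    res = {
        "right": {"lagging": 0, "total": 0},
        "left": {"lagging": 0, "total": 0},
    }
    for m in matches:
        off = (m.position - genome.ori_position) % L
        if off == 0 or m.position == genome.ter_position:
            logger.info("match at position %d lies exactly at ori/ter; "
                        "assigned by its leftmost base", m.position)
        rep = "right" if off < arc_right else "left"
        lagging = (m.strand == "+") == (rep == "right")
        res[rep]["total"] += 1
        res[rep]["lagging"] += lagging
    tot = res["right"]["total"] + res["left"]["total"]
    lag = res["right"]["lagging"] + res["left"]["lagging"]
    for rep in ("right", "left"):
        t = res[rep]["total"]
        res[rep]["fraction"] = res[rep]["lagging"] / t if t else float("nan")
    res["overall"] = {
        "lagging": lag,
        "total": tot,
        "fraction": lag / tot if tot else float("nan"),
    }
    return res


# ---------------------------------------------------------------------------
# Model / Results surface
# ---------------------------------------------------------------------------

class BoxDensityModel:
    """Positional-enrichment model of DnaA boxes on one circular replicon.

    Parameters
    ----------
    genome
        The replicon with its *oriC* anchor.
    motifs
        IUPAC motifs to scan for (default: consensus DnaA box TTWTNCACA and
        the relaxed datA/DARS class HHMTHCWVH).
    window_cs
        Sliding-window width in centisomes.
    mask_cs
        Optional circular interval to exclude before windowing (e.g. the
        *oriC* region itself).
    """

    def __init__(self, genome: CircularGenome,
                 motifs=DEFAULT_MOTIFS, window_cs: int = 10,
                 mask_cs: tuple[float, float] | None = None):
        self.genome = genome
        self.motifs = tuple(m.upper() for m in motifs)
        self.window_cs = window_cs
        self.mask_cs = mask_cs

    @classmethod
    def from_fasta(cls, path, ori_position: int, ter_position: int | None = None,
                   **kwargs) -> "BoxDensityModel":
        from Bio import SeqIO

        records = list(SeqIO.parse(str(path), "fasta"))
        if len(records) != 1:
            raise ValueError(f"expected one record in {path}, found {len(records)}")
        rec = records[0]
        genome = CircularGenome(id=rec.id, sequence=str(rec.seq),
                                ori_position=ori_position,
                                ter_position=ter_position)
        return cls(genome, **kwargs)

    def fit(self, nulls=("uniform", "permuted_motif"), n_sims: int = 1000,
            alpha: float = 0.05, kappa: float = 200.0, n_grid: int = 1000,
            neighborhood_cs: float = 5.0, seed: int | None = None
            ) -> "BoxDensityResults":
        matches = scan_motifs(self.genome, self.motifs)
        profile = window_counts(matches, self.window_cs, mask_cs=self.mask_cs)
        envelopes: dict[str, NullEnvelope] = {}
        regions: dict[str, list[tuple[int, int]]] = {}
        for kind in nulls:
            if kind == "uniform":
                env = uniform_null(profile, n_sims=n_sims, seed=seed)
            elif kind == "permuted_motif":
                env = permuted_motif_null(self.genome, self.motifs, profile,
                                          n_perm=n_sims, seed=seed,
                                          mask_cs=self.mask_cs)
            else:
                raise ValueError(f"unknown null kind {kind!r}")
            envelopes[kind] = env
            regions[kind] = significant_regions(env, alpha=alpha)
        kde = maxima = None
        if matches:
            kde = vonmises_zscore(matches, kappa=kappa, n_grid=n_grid)
            try:
                maxima = find_extrema(kde, neighborhood_cs=neighborhood_cs)
            except DegenerateProfileError:
                maxima = []
        return BoxDensityResults(self, matches, profile, envelopes, regions,
                                 kde, maxima, alpha=alpha, seed=seed)


class BoxDensityResults:
    """Fitted box-density analysis: matches, profile, envelopes, KDE."""

    def __init__(self, model, matches, profile, envelopes, regions,
                 kde, maxima, alpha, seed):
        self.model = model
        self.matches = matches
        self.profile = profile
        self.envelopes = envelopes
        self.regions = regions
        self.kde = kde
        self.maxima = maxima
        self.alpha = alpha
        self.seed = seed

    @property
    def n_matches(self) -> int:
        return len(self.matches)

    @property
    def global_maximum(self) -> Extremum | None:
        if not self.maxima:
            return None
        return next(m for m in self.maxima if m.is_global)

    def matches_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "chrom": self.model.genome.id,
                "position": [m.position for m in self.matches],
                "strand": [m.strand for m in self.matches],
                "motifs": [",".join(m.motifs_hit) for m in self.matches],
                "centisome": [m.centisome for m in self.matches],
            }
        )

    def matches_bed(self) -> str:
        """Matches as 6-column BED text (0-based half-open, score '.')."""
        lines = []
        motif_len = {m: len(m) for m in self.model.motifs}
        for m in self.matches:
            width = max(motif_len[x] for x in m.motifs_hit)
            lines.append("\t".join([
                self.model.genome.id, str(m.position), str(m.position + width),
                ",".join(m.motifs_hit), ".", m.strand,
            ]))
        return "\n".join(lines) + ("\n" if lines else "")

    def profile_dataframe(self):
        import pandas as pd

        data = {"center_cs": self.profile.centers, "count": self.profile.counts}
        for kind, env in self.envelopes.items():
            data[f"{kind}_lo"] = env.lo
            data[f"{kind}_hi"] = env.hi
            data[f"{kind}_pseudo_p"] = env.pseudo_p
        return pd.DataFrame(data)

    def summary(self) -> str:
        g = self.model.genome
        lines = [
            "DnaA box density analysis",
            "=" * 60,
            f"replicon: {g.id}  (L = {len(g):,} bp, ori @ {g.ori_position:,})",
            f"motifs:   {', '.join(self.model.motifs)}",
            f"matches:  {self.n_matches} unique (position,strand) sites",
            f"window:   {self.profile.window_cs} cs, step 1 cs",
        ]
        for kind, env in self.envelopes.items():
            regs = self.regions[kind]
            reg_s = ", ".join(f"[{a},{b}]" for a, b in regs) or "none"
            lines.append(
                f"{kind} null (n={env.n_sims}): significant regions "
                f"(pseudo-p < {self.alpha}): {reg_s}"
            )
        gm = self.global_maximum
        if gm is not None:
            lines.append(
                f"KDE global maximum: {gm.position_cs:.1f} cs "
                f"(Z = {gm.zscore:.2f}, {gm.dist_from_ori_cs:.1f} cs from oriC)"
            )
        return "\n".join(lines)

    def plot(self, ax=None):
        """Box counts per window with null envelopes, on a linear cs axis."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.profile.centers, self.profile.counts, "k-", label="observed")
        for kind, env in self.envelopes.items():
            ax.fill_between(self.profile.centers, env.lo, env.hi, alpha=0.3,
                            label=f"{kind} 5-95%")
        ax.set_xlabel("centisome from oriC")
        ax.set_ylabel(f"boxes / {self.profile.window_cs} cs window")
        ax.legend()
        return ax
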