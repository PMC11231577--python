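"""PWM motif scanning with exact null p-values.

Implements FIMO-style scanning: each position of a ±W window around a region
center is scored on both strands with the motif's log-odds matrix (bits,
relative to a 0-order background), and assigned an exact p-value from the
null score distribution computed by dynamic programming over discretized
per-column scores. Positions with p <= the cutoff (1e-5 by default) are
reported as hits.

Scores are discretized to a fixed bin width (0.01 bits by default) for both
the null table and the scanned windows, so reported p-values are exact for
the discretized statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .intervals import RegionSet, region_center

__all__ = [
    "PWM",
    "MotifHit",
    "PwmScorer",
    "read_meme",
    "write_meme",
    "read_pwm_tsv",
    "pvalue_table",
    "score_window",
    "scan_regions",
    "encode_sequence",
    "reverse_complement",
]

BASES = "ACGT"
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
# codes 0..3 = ACGT, 4 = N / other
_ENCODE_LUT = np.full(256, 4, dtype=np.uint8)
for _b, _c in _CODE.items():
    _ENCODE_LUT[ord(_b)] = _c
    _ENCODE_LUT[ord(_b.lower())] = _c

DEFAULT_PSEUDOCOUNT = 1e-4
DEFAULT_PRECISION = 0.01  # score bin width, bits
_N_BIN = -(10**7)  # sentinel column score for N: forces score far below any real one


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a DNA string to uint8 codes (A,C,G,T -> 0..3; anything else 4)."""
    return _ENCODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def reverse_complement(seq: str) -> str:
    comp = str.maketrans("ACGTNacgtn", "TGCANtgcan")
    return seq.translate(comp)[::-1]


@dataclass(frozen=True)
class PWM:
    """Position probability matrix with a 0-order background model.

    ``matrix`` has shape (W, 4) over A,C,G,T; each row sums to 1 (checked to
    1e-6). A pseudocount is added and rows renormalized before log-odds are
    taken, so observed bases never score -inf.
    """

    motif_id: str
    matrix: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        bg = np.asarray(self.background, dtype=float)
        object.__setattr__(self, "background", bg)
        if m.ndim != 2 or m.shape[1] != 4:
            raise ValueError("PWM matrix must have shape (W, 4)")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError(f"{self.motif_id}: PWM columns must sum to 1")
        if np.any(m < 0):
            raise ValueError(f"{self.motif_id}: PWM entries must be >= 0")
        if not np.isclose(bg.sum(), 1.0, atol=1e-6) or np.any(bg <= 0):
            raise ValueError("background must be positive and sum to 1")

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    def log_odds(self) -> np.ndarray:
        """Log-odds matrix in bits after pseudocount regularization."""
        p = self.matrix + self.pseudocount
        p = p / p.sum(axis=1, keepdims=True)
        return np.log2(p / self.background[None, :])

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=1))

    def reverse_complement(self) -> "PWM":
        return PWM(
            self.motif_id,
            self.matrix[::-1, ::-1].copy(),
            self.background[::-1].copy(),
            self.pseudocount,
        )

    def sample_site(self, rng: np.random.Generator) -> str:
        """Draw one site sequence from the probability matrix."""
        return "".join(
            BASES[rng.choice(4, p=row / row.sum())] for row in self.matrix
        )

    def with_background(self, background: np.ndarray) -> "PWM":
        return PWM(self.motif_id, self.matrix, background, self.pseudocount)


@dataclass(frozen=True)
class MotifHit:
    """One scored motif occurrence inside a region's scan window."""

    region_id: str
    motif_id: str
    offset: int  # motif midpoint minus region center, bp
    strand: str
    score_bits: float
    p_value: float


# ---------------------------------------------------------------------------
# Motif file I/O


def read_meme(path: str | Path) -> list[PWM]:
    """Read motifs from a minimal MEME file (letter-probability matrices)."""
    pwms: list[PWM] = []
    background = np.full(4, 0.25)
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            i += 1
            toks = lines[i].split()
            freqs = {toks[j]: float(toks[j + 1]) for j in range(0, len(toks), 2)}
            background = np.array([freqs[b] for b in BASES])
        elif line.startswith("MOTIF"):
            motif_id = line.split()[1]
            while not lines[i].strip().startswith("letter-probability matrix"):
                i += 1
            header = lines[i]
            width = int(header.split("w=")[1].split()[0])
            rows = []
            for k in range(width):
                i += 1
                rows.append([float(x) for x in lines[i].split()])
            pwms.append(PWM(motif_id, np.array(rows), background))
        i += 1
    if not pwms:
        raise ValueError(f"{path}: no MOTIF records found")
    return pwms


def write_meme(pwms: Sequence[PWM], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        bg = pwms[0].background
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {bg[i]:.6f}" for i, b in enumerate(BASES)) + "\n\n")
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.motif_id}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {pwm.width} "
                f"nsites= 20 E= 0\n"
            )
            for row in pwm.matrix:
                fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")


def read_pwm_tsv(path: str | Path) -> list[PWM]:
    """Read the plain TSV dialect: columns motif_id, position, A, C, G, T."""
    df = pd.read_csv(path, sep="\t")
    pwms = []
    for motif_id, grp in df.groupby("motif_id", sort=False):
        grp = grp.sort_values("position")
        pwms.append(PWM(str(motif_id), grp[list(BASES)].to_numpy(float)))
    return pwms


# ---------------------------------------------------------------------------
# Scoring and exact p-values


def score_window(pwm: PWM, seq: str) -> float:
    """Exact log-odds score (bits) of one W-mer; -inf if it contains N."""
    if len(seq) != pwm.width:
        raise ValueError(f"sequence length {len(seq)} != motif width {pwm.width}")
    codes = encode_sequence(seq)
    if np.any(codes == 4):
        return float("-inf")
    lom = pwm.log_odds()
    return float(lom[np.arange(pwm.width), codes].sum())


class PwmScorer:
    """Discretized scorer for one PWM: binned log-odds plus exact null SF.

    Per-column scores are rounded to integer multiples of ``precision`` bits;
    the null distribution of the binned window score under the background is
    computed by dynamic-programming convolution across columns. P-values are
    the survival function P(binned score >= s | background).
    """

    def __init__(self, pwm: PWM, precision: float = DEFAULT_PRECISION) -> None:
        if precision <= 0:
            raise ValueError("precision must be > 0")
        self.pwm = pwm
        self.precision = precision
        lom = pwm.log_odds()
        bins = np.rint(lom / precision).astype(np.int64)  # (W, 4)
        self.bins = np.concatenate(
            [bins, np.full((pwm.width, 1), _N_BIN, dtype=np.int64)], axis=1
        )  # (W, 5): column 4 is the N sentinel
        self.min_bin = int(bins.min(axis=1).sum())
        self.max_bin = int(bins.max(axis=1).sum())
        self._sf = self._null_sf(bins, pwm.background)

    def _null_sf(self, bins: np.ndarray, bg: np.ndarray) -> np.ndarray:
        """Survival function over binned scores [min_bin, max_bin] via DP."""
        lo = bins.min(axis=1).cumsum()
        hi = bins.max(axis=1).cumsum()
        dist = np.array([1.0])
        cur_lo = 0
        for k in range(bins.shape[0]):
            size = hi[k] - lo[k] + 1
            new = np.zeros(size)
            for b in range(4):
                off = bins[k, b]
                start = cur_lo + off - lo[k]
                new[start : start + dist.size] += bg[b] * dist
            dist = new
            cur_lo = lo[k]
        # reversed cumsum -> P(S >= s); clip tiny negative float error
        sf = np.cumsum(dist[::-1])[::-1]
        return np.clip(sf, 0.0, 1.0)

    def pvalue_of_bin(self, binsum: np.ndarray | int) -> np.ndarray | float:
        """P(null binned score >= binsum); 1 below range, exact inside."""
        idx = np.asarray(binsum) - self.min_bin
        scalar = idx.ndim == 0
        idx = np.atleast_1d(idx)
        out = np.ones(idx.shape, dtype=float)
        inside = (idx >= 0) & (idx < self._sf.size)
        out[inside] = self._sf[idx[inside]]
        out[idx >= self._sf.size] = 0.0
        return float(out[0]) if scalar else out

    def pvalue(self, score_bits: float) -> float:
        """P-value of a (possibly exact) score, discretized like the table."""
        if score_bits == float("-inf"):
            return 1.0
        return float(self.pvalue_of_bin(int(np.rint(score_bits / self.precision))))

    def score_table(self) -> pd.DataFrame:
        """The full null table: binned score (bits) -> survival probability."""
        bins = np.arange(self.min_bin, self.max_bin + 1)
        return pd.DataFrame(
            {"score_bits": bins * self.precision, "p_value": self._sf}
        )


def pvalue_table(pwm: PWM, precision: float = DEFAULT_PRECISION) -> pd.DataFrame:
    """Exact null distribution of the discretized score as a score -> p table."""
    return PwmScorer(pwm, precision).score_table()


# ---------------------------------------------------------------------------
# Window scanning


def estimate_background(genome: Mapping[str, str]) -> np.ndarray:
    """0-order background frequencies from the scanned genome (N excluded).

    Counts are symmetrized over complementary bases (A with T, C with G), so
    the background is strand-invariant and reverse-strand p-values share the
    forward-strand null table exactly.
    """
    counts = np.zeros(4, dtype=np.int64)
    for seq in genome.values():
        codes = encode_sequence(str(seq))
        counts += np.bincount(codes[codes < 4], minlength=4)
    if counts.sum() == 0:
        raise ValueError("genome contains no A/C/G/T bases")
    counts = counts + counts[::-1]  # complement of (A,C,G,T) is (T,G,C,A)
    return counts / counts.sum()


def _window_bounds(
    iv_center: int, chrom_len: int, halfwidth: int
) -> tuple[int, int]:
    return max(0, iv_center - halfwidth), min(chrom_len, iv_center + halfwidth)


def scan_regions(
    genome: Mapping[str, str],
    regions: RegionSet,
    pwms: Sequence[PWM],
    cfg: AnalysisConfig | None = None,
    precision: float = DEFAULT_PRECISION,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Scan ±halfwidth windows around region centers with every PWM.

    Both strands are scanned (reverse strand as the reverse complement of the
    window). Every position with p <= ``cfg.fimo_p_cutoff`` is reported.
    Windows are clipped at chromosome ends; clipped or N positions never hit.

    Returns ``(hits, hit_indicator)``: hits is a DataFrame with one row per
    passing position (region_id, motif_id, offset, strand, score_bits,
    p_value, best), where ``best`` marks the region/motif best hit (lowest p,
    then smallest \\|offset\\|, then + strand); hit_indicator is a boolean
    regions x motifs DataFrame.
    """
    cfg = cfg or AnalysisConfig()
    half = cfg.scan_window_halfwidth
    chrom_codes = {c: encode_sequence(str(s)) for c, s in genome.items()}
    n = len(regions)
    names = [iv.name for iv in regions]

    # Assemble fixed-width window matrix, padding clipped flanks with N.
    width_total = 2 * half
    X = np.full((n, width_total), 4, dtype=np.uint8)
    centers = np.empty(n, dtype=np.int64)
    starts = np.empty(n, dtype=np.int64)
    for i, iv in enumerate(regions):
        if iv.chrom not in chrom_codes:
            raise ValueError(f"region {iv.name}: chromosome {iv.chrom} not in genome")
        codes = chrom_codes[iv.chrom]
        c = region_center(iv)
        if not (0 <= c < codes.size):
            raise ValueError(f"region {iv.name}: center {c} outside chromosome")
        ws, we = _window_bounds(c, codes.size, half)
        X[i, ws - (c - half) : we - (c - half)] = codes[ws:we]
        centers[i] = c
        starts[i] = c - half  # genome coordinate of window column 0 (may be < 0)

    records: list[tuple] = []
    indicator = np.zeros((n, len(pwms)), dtype=bool)
    positions = None
    for m_idx, pwm in enumerate(pwms):
        W = pwm.width
        if W > width_total:
            continue
        scorer = PwmScorer(pwm, precision)
        n_pos = width_total - W + 1
        if positions is None or positions.size != n_pos:
            positions = np.arange(n_pos)
        for strand, bins in (
            ("+", scorer.bins),
            ("-", scorer.bins[::-1, [3, 2, 1, 0, 4]]),
        ):
            S = np.zeros((n, n_pos), dtype=np.int64)
            for k in range(W):
                S += bins[k][X[:, k : k + n_pos]]
            pv = scorer.pvalue_of_bin(S)
            # N-containing windows carry the sentinel and can only pass at
            # cutoff ~1; mask them explicitly so they are never hits.
            valid = S > _N_BIN // 2
            mask = (pv <= cfg.fimo_p_cutoff) & valid
            ridx, cidx = np.nonzero(mask)
            if ridx.size == 0:
                continue
            indicator[np.unique(ridx), m_idx] = True
            site_start = starts[ridx] + cidx
            offset = site_start + W // 2 - centers[ridx]
            for r, c_, off, s_, p_ in zip(
                ridx, cidx, offset, S[ridx, cidx], pv[ridx, cidx]
            ):
                records.append(
                    (
                        names[r],
                        pwm.motif_id,
                        int(off),
                        strand,
                        float(s_ * precision),
                        float(p_),
                    )
                )

    hits = pd.DataFrame(
        records,
        columns=["region_id", "motif_id", "offset", "strand", "score_bits", "p_value"],
    )
    if len(hits):
        order = hits.assign(
            _absoff=hits.offset.abs(), _minus=(hits.strand == "-")
        ).sort_values(
            ["region_id", "motif_id", "p_value", "_absoff", "_minus"],
            kind="mergesort",
        )
        best_idx = order.groupby(["region_id", "motif_id"], sort=False).head(1).index
        hits["best"] = False
        hits.loc[best_idx, "best"] = True
    else:
        hits["best"] = pd.Series(dtype=bool)
    hit_indicator = pd.DataFrame(
        indicator, index=pd.Index(names, name="region_id"),
        columns=[p.motif_id for p in pwms],
    )
    return hits, hit_indicator


def load_genome(path: str | Path) -> dict[str, str]:
    """Load a FASTA genome into memory as chrom -> sequence."""
    from pyfaidx import Fasta

    with Fasta(str(path)) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}
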