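"""Splice-site and splicing-regulatory-element motif strength.

Splicing regulatory elements (exonic/intronic enhancers and silencers,
ESE/ESS/ISE/ISS) and RNA-binding-protein motifs are represented as
log-odds position weight matrices (log2 of position frequency over the
0.25 background).  A PWM's detection threshold is the 95th percentile of
its scores over all 4^width k-mers.  Mutation effects are the summed
score changes of the windows that overlap the mutated position(s) and
clear the threshold in either allele, averaged (non-zero values only)
within each category; enhancer and silencer aggregates sum the exonic
and intronic category averages.

The donor (5' splice) site is scored over the 9-mer of the last three
exonic and first six intronic nucleotides with a pluggable scorer; the
default is a log-odds matrix built from consensus frequencies of
annotated human donor sites, and an external maximum-entropy score table
can be loaded instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .junction import JunctionSequence

SRE_CATEGORIES = ("ESE", "ESS", "ISE", "ISS")
RBP_CATEGORIES = ("RBP-inclusion", "RBP-exclusion")
_BASES = "ACGU"
_IDX = {b: i for i, b in enumerate(_BASES)}


@dataclass(frozen=True)
class MotifPWM:
    """A log-odds motif matrix with its exhaustive-percentile threshold."""

    name: str
    category: str
    matrix: np.ndarray          # (width, 4) log2 odds
    threshold: float = field(default=None)

    def __post_init__(self):
        m = np.asarray(self.matrix, float)
        if m.ndim != 2 or m.shape[1] != 4:
            raise ValueError("matrix must be (width, 4)")
        if m.shape[0] < 4:
            raise ValueError("PWM width must be >= 4")
        object.__setattr__(self, "matrix", m)
        if self.threshold is None:
            object.__setattr__(self, "threshold", pwm_threshold_matrix(m))

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    def score(self, kmer: str) -> float:
        return float(sum(self.matrix[p, _IDX[b]] for p, b in enumerate(kmer)))

    def scan(self, sequence: str) -> np.ndarray:
        """Window scores at every start position (1-based start i maps to
        index i-1); windows truncated by the sequence end are skipped."""
        n = len(sequence) - self.width + 1
        if n <= 0:
            return np.empty(0)
        enc = np.array([_IDX[b] for b in sequence])
        out = np.zeros(n)
        for p in range(self.width):
            out += self.matrix[p, enc[p:p + n]]
        return out


def enumerate_kmer_scores(matrix: np.ndarray) -> np.ndarray:
    """Scores of all 4^width k-mers (iterated outer sums, no explicit
    k-mer strings)."""
    scores = np.zeros(1)
    for row in matrix:
        scores = (scores[:, None] + row[None, :]).ravel()
    return scores


def pwm_threshold_matrix(matrix: np.ndarray, percentile: float = 95.0
                         ) -> float:
    if matrix.shape[0] > 10:
        raise ValueError("exhaustive threshold limited to width <= 10")
    return float(np.percentile(enumerate_kmer_scores(matrix), percentile))


def pwm_threshold(pwm: MotifPWM, percentile: float = 95.0) -> float:
    """95th percentile of the exhaustive k-mer score list."""
    return pwm_threshold_matrix(pwm.matrix, percentile)


def pwm_from_hexamers(hexamers, category: str, name: str = "",
                      pseudocount: float = 0.5) -> MotifPWM:
    """Build a log-odds PWM from a k-mer set.

    Frequencies (with ``pseudocount`` added per base per position) are
    normalized to the 0.25 background and log2-transformed, so a
    position frequency of 0.5 maps to a weight of exactly 1.0.
    """
    kmers = sorted(set(k.upper().replace("T", "U") for k in hexamers))
    if not kmers:
        raise ValueError("empty k-mer set")
    widths = {len(k) for k in kmers}
    if len(widths) != 1:
        raise ValueError("k-mers must share a single width")
    w = widths.pop()
    counts = np.zeros((w, 4))
    for k in kmers:
        for p, b in enumerate(k):
            counts[p, _IDX[b]] += 1
    freqs = (counts + pseudocount) / (len(kmers) + 4 * pseudocount)
    matrix = np.log2(freqs / 0.25)
    return MotifPWM(name or f"{category}_pwm", category, matrix)


# ---------------------------------------------------------------------------
# Mutation delta-strengths
# ---------------------------------------------------------------------------

def _window_bounds(pwm: MotifPWM, js: JunctionSequence) -> tuple[int, int]:
    """Allowed 1-based window start range [lo, hi] for a PWM's compartment.

    Exonic PWMs scan windows fully inside the exon, intronic ones fully
    inside the intron; junction-straddling windows are skipped.  RBP
    motifs scan the whole sequence.
    """
    w = pwm.width
    if pwm.category in ("ESE", "ESS"):
        return 1, js.junction_offset - w + 1
    if pwm.category in ("ISE", "ISS"):
        return js.junction_offset + 1, len(js) - w + 1
    return 1, len(js) - w + 1


def pwm_delta(pwm: MotifPWM, js: JunctionSequence, mutant: str,
              mutated_positions) -> float:
    """Summed above-threshold score change over windows covering a
    mutated position (threshold test on max(WT, mutant) window score)."""
    lo, hi = _window_bounds(pwm, js)
    if hi < lo:
        return 0.0
    w = pwm.width
    wt_scores = pwm.scan(js.sequence)
    mut_scores = pwm.scan(mutant)
    delta = 0.0
    starts = set()
    for pos in mutated_positions:
        for s in range(max(lo, pos - w + 1), min(hi, pos) + 1):
            starts.add(s)
    for s in starts:
        wt_s, mut_s = wt_scores[s - 1], mut_scores[s - 1]
        if max(wt_s, mut_s) > pwm.threshold:
            delta += mut_s - wt_s
    return float(delta)


def _category_average(deltas) -> float:
    nz = [d for d in deltas if d != 0.0]
    return float(np.mean(nz)) if nz else 0.0


@dataclass(frozen=True)
class DeltaStrengths:
    """Per-category and aggregate motif strength changes for a mutation."""

    delta_ss: float
    per_category: dict
    per_pwm: dict
    rbp_exclusion: float = 0.0
    rbp_inclusion: float = 0.0

    @property
    def enhancer(self) -> float:
        return self.per_category.get("ESE", 0.0) + \
            self.per_category.get("ISE", 0.0)

    @property
    def silencer(self) -> float:
        return self.per_category.get("ESS", 0.0) + \
            self.per_category.get("ISS", 0.0)

    def as_features(self) -> dict:
        return {"delta_ss": self.delta_ss, "enhancer": self.enhancer,
                "silencer": self.silencer, "rbp_ex": self.rbp_exclusion,
                "rbp_in": self.rbp_inclusion}


def delta_strength(pwms, js: JunctionSequence, mutant: str,
                   splice_model: "SpliceSiteModel | None" = None,
                   rbp_pwms=()) -> DeltaStrengths:
    """All motif-strength changes between wild type and one mutant."""
    if len(mutant) != len(js):
        raise ValueError("mutant and wild type must have equal length")
    mutated = [i + 1 for i, (a, b) in enumerate(zip(js.sequence, mutant))
               if a != b]
    per_pwm = {}
    by_cat = {c: [] for c in SRE_CATEGORIES}
    for pwm in pwms:
        d = pwm_delta(pwm, js, mutant, mutated)
        per_pwm[pwm.name] = d
        by_cat[pwm.category].append(d)
    per_category = {c: _category_average(v) for c, v in by_cat.items()}
    ex, inc = rbp_delta(rbp_pwms, js, mutant) if rbp_pwms else (0.0, 0.0)
    dss = (splice_site_delta(js, mutant, splice_model)
           if splice_model is not None else 0.0)
    return DeltaStrengths(dss, per_category, per_pwm, ex, inc)


def rbp_delta(pwms, js: JunctionSequence, mutant: str
              ) -> tuple[float, float]:
    """(exclusion, inclusion) aggregate RBP motif strength changes."""
    mutated = [i + 1 for i, (a, b) in enumerate(zip(js.sequence, mutant))
               if a != b]
    ex, inc = [], []
    for pwm in pwms:
        d = pwm_delta(pwm, js, mutant, mutated)
        (ex if pwm.category == "RBP-exclusion" else inc).append(d)
    return _category_average(ex), _category_average(inc)


# ---------------------------------------------------------------------------
# Donor-site scoring
# ---------------------------------------------------------------------------

#: consensus base frequencies of annotated human donor sites over the
#: 9-mer (last 3 exonic, first 6 intronic positions); near-invariant
#: GU at +1/+2
_DONOR_CONSENSUS_FREQS = np.array([
    # A     C     G     U
    [0.33, 0.37, 0.18, 0.12],   # -3
    [0.60, 0.13, 0.13, 0.14],   # -2
    [0.09, 0.03, 0.80, 0.08],   # -1
    [0.004, 0.003, 0.990, 0.003],  # +1
    [0.003, 0.003, 0.004, 0.990],  # +2
    [0.60, 0.03, 0.32, 0.05],   # +3
    [0.70, 0.08, 0.12, 0.10],   # +4
    [0.08, 0.05, 0.84, 0.03],   # +5
    [0.17, 0.19, 0.19, 0.45],   # +6
])


class SpliceSiteModel:
    """Pluggable scorer for the 9-nt donor site (3 exonic + 6 intronic).

    The default is a first-order log2-odds matrix over the nine positions
    built from donor-site consensus frequencies.  ``from_score_table``
    loads an external lookup (e.g. a maximum-entropy 9-mer table, one
    ``<9-mer><tab><score>`` row per line).
    """

    EXONIC, INTRONIC = 3, 6

    def __init__(self, matrix: np.ndarray | None = None,
                 score_table: dict | None = None):
        self._table = score_table
        if score_table is None:
            freqs = matrix if matrix is not None else _DONOR_CONSENSUS_FREQS
            freqs = np.asarray(freqs, float)
            if freqs.shape != (9, 4):
                raise ValueError("donor matrix must be (9, 4)")
            if np.allclose(freqs.sum(axis=1), 1.0, atol=0.05):
                self.matrix = np.log2(freqs / 0.25)
            else:  # already log-odds
                self.matrix = freqs
        else:
            self.matrix = None

    @classmethod
    def from_score_table(cls, path) -> "SpliceSiteModel":
        table = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                kmer, score = line.split()
                table[kmer.upper().replace("T", "U")] = float(score)
        return cls(score_table=table)

    def score(self, nine_mer: str) -> float:
        if len(nine_mer) != 9:
            raise ValueError("donor site must be a 9-mer")
        nine_mer = nine_mer.upper().replace("T", "U")
        if self._table is not None:
            return self._table[nine_mer]
        return float(sum(self.matrix[p, _IDX[b]]
                         for p, b in enumerate(nine_mer)))

    def donor_site(self, js: JunctionSequence, sequence: str | None = None
                   ) -> str:
        seq = sequence if sequence is not None else js.sequence
        off = js.junction_offset
        if off < self.EXONIC or off + self.INTRONIC > len(seq):
            raise ValueError("sequence too short around the junction")
        return seq[off - self.EXONIC: off + self.INTRONIC]


def splice_site_delta(js: JunctionSequence, mutant: str,
                      model: SpliceSiteModel | None = None) -> float:
    """Donor strength change; 0 unless a mutated position lies in the
    9-mer.  Positive values mean a stronger donor site."""
    model = model or SpliceSiteModel()
    lo = js.junction_offset - model.EXONIC + 1
    hi = js.junction_offset + model.INTRONIC
    mutated = [i + 1 for i, (a, b) in enumerate(zip(js.sequence, mutant))
               if a != b]
    if not any(lo <= p <= hi for p in mutated):
        return 0.0
    return model.score(model.donor_site(js, mutant)) - \
        model.score(model.donor_site(js))


# ---------------------------------------------------------------------------
# Plain-text I/O
# ---------------------------------------------------------------------------

def read_hexamer_file(path, category: str, name: str = "") -> MotifPWM:
    """One k-mer per line -> PWM."""
    with open(path) as fh:
        kmers = [ln.strip() for ln in fh if ln.strip()
                 and not ln.startswith("#")]
    return pwm_from_hexamers(kmers, category, name)


def write_pwm_tsv(pwm: MotifPWM, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# name={pwm.name} category={pwm.category} "
                 f"threshold={pwm.threshold:.6f}\n")
        fh.write("pos\tA\tC\tG\tU\n")
        for p, row in enumerate(pwm.matrix, start=1):
            fh.write(f"{p}\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")


def read_pwm_tsv(path) -> MotifPWM:
    meta = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                for tok in line[1:].split():
                    if "=" in tok:
                        k, v = tok.split("=", 1)
                        meta[k] = v
            elif line.strip() and not line.startswith("pos"):
                rows.append([float(x) for x in line.split()[1:5]])
    return MotifPWM(meta.get("name", "pwm"), meta.get("category", "ESE"),
                    np.array(rows),
                    float(meta["threshold"]) if "threshold" in meta else None)
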