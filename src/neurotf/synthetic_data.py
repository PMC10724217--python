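"""Synthetic inputs with planted ground truth for the whole pipeline.

Everything downstream of wet-lab data (guide libraries, sorted-population
screen counts, toy genomes with planted regulator motifs, expression and ATAC
time courses) can be generated here with a known answer, so that screen
scoring, motif scanning, differential expression and network inference are
testable end-to-end without any external download.

The defaults mirror the study design this package targets: a library of 1891
TFs x 10 guides plus 1000 non-targeting controls, a sparse reporter-negative
sorted population in which most guides are lowly represented or absent,
negative-binomial expression/accessibility counts with 4 replicates per
timepoint, and seed regulators NEUROG1/NEUROG2 initiating a planted
regulator->target hierarchy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

BASES = np.array(list("ACGT"))

#: populations sequenced in a sorted differentiation screen
POPULATIONS = (
    "plasmid",
    "esc_input",
    "unsorted_iN",
    "sorted_negative",
    "sorted_positive",
    "no_dox",
)

#: temporal archetypes used for planted expression profiles
PATTERNS = ("early-up", "late-up", "up-then-down", "flat")

ACTIVATING = "activating"
REPRESSING = "repressing"


class PlantedEdge(NamedTuple):
    """A ground-truth regulatory interaction: regulator -> target at ``onset``."""

    regulator: str
    target: str
    onset: str
    sign: str


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design parameters for all synthetic generators.

    Parameters
    ----------
    n_tf, guides_per_tf, n_ntc:
        Library design: targeted TF count, guides per TF, and the number of
        non-targeting control guides used to build empirical nulls.
    n_essential:
        Number of planted differentiation-essential TFs in the screen.
    enrichment_effect:
        Multiplicative abundance gain of essential-TF guides in the sorted
        reporter-negative population (cells that failed to differentiate).
    capture_prob:
        Probability that a non-essential targeting guide appears at all in the
        sparse sorted-negative population (stringent sort gate).
    depth:
        Total sequencing reads drawn per population.
    timepoints:
        Ordered timepoint labels; the first is the ESC (pre-induction)
        baseline for every contrast.
    n_replicates:
        Biological replicates per timepoint for expression counts.
    n_atac_replicates:
        Biological replicates per timepoint for ATAC peak counts.
    dispersion:
        Negative-binomial dispersion (variance = mu + dispersion * mu^2).
    seed:
        Master RNG seed; a fixed seed gives byte-identical outputs.
    """

    n_tf: int = 1891
    guides_per_tf: int = 10
    n_ntc: int = 1000
    n_essential: int = 20
    enrichment_effect: float = 20.0
    capture_prob: float = 0.05
    depth: int = 1_000_000
    timepoints: tuple[str, ...] = ("ESC", "12h", "D1", "D4")
    n_replicates: int = 4
    n_atac_replicates: int = 2
    dispersion: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_tf", "guides_per_tf", "n_ntc", "depth", "n_replicates",
                     "n_atac_replicates"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.n_essential < 0 or self.n_essential > self.n_tf:
            raise ValueError("n_essential must lie in [0, n_tf]")
        if not (0.0 < self.capture_prob <= 1.0):
            raise ValueError("capture_prob must be in (0, 1]")
        if self.enrichment_effect < 1.0:
            raise ValueError("enrichment_effect must be >= 1")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if len(self.timepoints) < 2:
            raise ValueError("need a baseline plus at least one later timepoint")


@dataclass(frozen=True)
class GroundTruth:
    """Planted truth against which parameter recovery is measured."""

    essential_tfs: frozenset[str] = frozenset()
    planted_edges: tuple[PlantedEdge, ...] = ()
    planted_cluster: Mapping[str, str] = field(default_factory=dict)
    #: TFs whose loss impairs stem-cell fitness (deplete during culture)
    dropout_tfs: frozenset[str] = frozenset()

    def regulators(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.planted_edges:
            seen.setdefault(e.regulator)
        return list(seen)

    def validate(self, tf_names: Iterable[str],
                 config: SyntheticConfig | None = None) -> None:
        known = set(tf_names)
        unknown = (set(self.essential_tfs) | set(self.dropout_tfs)
                   | {e.regulator for e in self.planted_edges}
                   | {e.target for e in self.planted_edges}) - known
        if unknown:
            raise ValueError(f"ground truth references unknown TFs: {sorted(unknown)[:5]}")
        for e in self.planted_edges:
            if config is not None and e.onset not in config.timepoints[1:]:
                raise ValueError(f"edge onset {e.onset!r} not a post-baseline timepoint")
            if e.sign not in (ACTIVATING, REPRESSING):
                raise ValueError(f"bad edge sign {e.sign!r}")
        bad = {p for p in self.planted_cluster.values() if p not in PATTERNS}
        if bad:
            raise ValueError(f"unknown expression patterns: {bad}")


def tf_symbols(n_tf: int) -> list[str]:
    """Synthetic TF namespace; the two seed pioneer factors come first."""
    if n_tf <= 0:
        raise ValueError("n_tf must be positive")
    names = ["NEUROG1", "NEUROG2"][:n_tf]
    names += [f"TF{i:04d}" for i in range(3, n_tf + 1)]
    return names


def _random_kmers(rng: np.random.Generator, n: int, k: int = 20,
                  max_tries: int = 50) -> list[str]:
    """Distinct random DNA k-mers (collision retry is bounded)."""
    seen: set[str] = set()
    out: list[str] = []
    for _ in range(max_tries):
        need = n - len(out)
        if need == 0:
            break
        draws = rng.integers(0, 4, size=(need, k))
        for row in draws:
            s = "".join(BASES[row])
            if s not in seen:
                seen.add(s)
                out.append(s)
    if len(out) < n:
        raise RuntimeError("could not generate distinct guide sequences")
    return out


def generate_library(config: SyntheticConfig) -> pd.DataFrame:
    """Guide library manifest: n_tf x guides_per_tf targeting + n_ntc controls.

    Returns a DataFrame with columns ``guide_id, gene, is_ntc, sequence``;
    non-targeting rows have ``gene`` = NA and ``is_ntc`` = True.
    """
    rng = np.random.default_rng([config.seed, 11])
    tfs = tf_symbols(config.n_tf)
    n_guides = config.n_tf * config.guides_per_tf + config.n_ntc
    seqs = _random_kmers(rng, n_guides)
    rows = []
    i = 0
    for tf in tfs:
        for g in range(config.guides_per_tf):
            rows.append((f"{tf}_g{g + 1}", tf, False, seqs[i]))
            i += 1
    for j in range(config.n_ntc):
        rows.append((f"NTC_{j + 1:04d}", pd.NA, True, seqs[i]))
        i += 1
    return pd.DataFrame(rows, columns=["guide_id", "gene", "is_ntc", "sequence"])


def make_screen_truth(config: SyntheticConfig) -> GroundTruth:
    """Pick ``n_essential`` differentiation-essential TFs at random (never the seeds)."""
    rng = np.random.default_rng([config.seed, 13])
    candidates = [t for t in tf_symbols(config.n_tf) if not t.startswith("NEUROG")]
    if config.n_essential > len(candidates):
        raise ValueError("n_essential exceeds available non-seed TFs")
    chosen = rng.choice(len(candidates), size=config.n_essential, replace=False)
    return GroundTruth(essential_tfs=frozenset(candidates[i] for i in sorted(chosen)))


def simulate_screen(manifest: pd.DataFrame, truth: GroundTruth,
                    config: SyntheticConfig) -> pd.DataFrame:
    """Simulate guide counts for all sorted/unsorted screen populations.

    Baseline abundances are log-normal(0, 0.5).  In the sorted-negative
    population, guides of essential TFs gain ``enrichment_effect``-fold
    abundance while other targeting guides survive the stringent sort gate
    only with probability ``capture_prob``; non-targeting guides are unchanged
    in expectation everywhere.  Counts are multinomial draws at ``depth``
    reads per population.  Fitness-essential ``dropout_tfs`` deplete in every
    cellular population relative to the plasmid pool.
    """
    genes = manifest["gene"]
    truth.validate(genes.dropna().unique(), config)

    rng = np.random.default_rng([config.seed, 17])
    n = len(manifest)
    baseline = rng.lognormal(mean=0.0, sigma=0.5, size=n)

    is_essential = genes.isin(truth.essential_tfs).to_numpy()
    is_dropout = genes.isin(truth.dropout_tfs).to_numpy()
    is_targeting = ~manifest["is_ntc"].to_numpy()

    cellular = baseline.copy()
    cellular[is_dropout & is_targeting] *= 0.1  # fitness dropout during culture

    abund = {
        "plasmid": baseline,
        "esc_input": cellular,
        "no_dox": cellular,
        "unsorted_iN": cellular,
        "sorted_positive": cellular,
    }
    neg = cellular.copy()
    neg[is_essential & is_targeting] *= config.enrichment_effect
    captured = rng.random(n) < config.capture_prob
    keep = (~is_targeting) | (is_essential & is_targeting) | captured
    neg = np.where(keep, neg, 0.0)
    abund["sorted_negative"] = neg

    counts = {}
    for pop in POPULATIONS:
        p = abund[pop] / abund[pop].sum()
        counts[pop] = rng.multinomial(config.depth, p)
    return pd.DataFrame(counts, index=manifest["guide_id"].to_numpy())


# ---------------------------------------------------------------------------
# Toy genome with planted motifs
# ---------------------------------------------------------------------------

GENE_SLOT = 10_000          # one gene per 10 kb slot
BODY_OFFSET = 2_500         # gene body position within the slot
BODY_LEN = 4_000
UPSTREAM = 2_000            # cis-regulatory upstream window
PEAK_LEN = 200              # planted peak-sized windows
WINDOW_SPACING = 300
PWM_LEN = 8
PWM_DOMINANT = 0.85


@dataclass
class ToyGenome:
    """Gene models, chromosome sequence, regulator PWMs and planted placements."""

    genes: pd.DataFrame            # gene, chrom, start, end, strand
    sequences: dict[str, str]      # chrom -> sequence
    pwms: dict[str, np.ndarray]    # regulator -> 4 x L probability matrix
    peaks: pd.DataFrame            # peak_id, chrom, start, end
    placements: pd.DataFrame       # regulator, target, peak_id, offset, strand

    def consensus(self, regulator: str) -> str:
        return "".join(BASES[np.argmax(self.pwms[regulator], axis=0)])

    def peak_sequences(self) -> dict[str, str]:
        out = {}
        for row in self.peaks.itertuples():
            out[row.peak_id] = self.sequences[row.chrom][row.start:row.end]
        return out


def _make_pwms(regulators: Sequence[str], rng: np.random.Generator,
               max_tries: int = 200) -> dict[str, np.ndarray]:
    """One-dominant-base PWMs (0.85 / 3 x 0.05) with pairwise-distinct consensi."""
    pwms: dict[str, np.ndarray] = {}
    seen: set[str] = set()
    for reg in regulators:
        for _ in range(max_tries):
            dom = rng.integers(0, 4, size=PWM_LEN)
            consensus = "".join(BASES[dom])
            if consensus not in seen:
                seen.add(consensus)
                mat = np.full((4, PWM_LEN), (1 - PWM_DOMINANT) / 3)
                mat[dom, np.arange(PWM_LEN)] = PWM_DOMINANT
                pwms[reg] = mat
                break
        else:
            raise RuntimeError("could not draw distinct PWM consensi")
    return pwms


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def generate_toy_genome(truth: GroundTruth, n_tf: int, seed: int = 0) -> ToyGenome:
    """Build a synthetic chromosome whose planted edges are motif-discoverable.

    Each TF occupies a 10 kb slot with a 4 kb gene body (strand alternating).
    For every planted edge R->T, a 200 bp peak-sized window inside T's
    cis-regulatory region (gene body + 2 kb upstream, allocated upstream
    first) receives one exact-consensus occurrence of R's PWM.  A background
    peak without planted motifs is added per gene.  All placements are
    recorded so recovery can be asserted exactly.
    """
    if n_tf < 2:
        raise ValueError("need at least two TFs for a regulator and a target")
    tfs = tf_symbols(n_tf)
    truth.validate(tfs)
    rng = np.random.default_rng([seed, 19])
    chrom = "chrS"
    length = n_tf * GENE_SLOT
    seq = rng.integers(0, 4, size=length)

    rows = []
    for i, tf in enumerate(tfs):
        start = i * GENE_SLOT + BODY_OFFSET
        rows.append((tf, chrom, start, start + BODY_LEN, "+" if i % 2 == 0 else "-"))
    genes = pd.DataFrame(rows, columns=["gene", "chrom", "start", "end", "strand"])
    gene_ix = genes.set_index("gene")

    regulators = truth.regulators()
    pwms = _make_pwms(regulators, rng)

    peaks = []
    placements = []
    windows_used: dict[str, int] = {}
    capacity = (UPSTREAM + BODY_LEN) // WINDOW_SPACING - 1

    def _window(target: str, k: int) -> tuple[int, int]:
        g = gene_ix.loc[target]
        if g.strand == "+":
            # upstream lies below the body start; spill into the body if needed
            w_start = g.start - UPSTREAM + 100 + k * WINDOW_SPACING
        else:
            w_start = g.end + UPSTREAM - 100 - PEAK_LEN - k * WINDOW_SPACING
        return int(w_start), int(w_start) + PEAK_LEN

    for e in truth.planted_edges:
        k = windows_used.get(e.target, 0)
        if k >= capacity:
            raise RuntimeError(f"no free motif window left in CRE of {e.target}")
        windows_used[e.target] = k + 1
        w_start, w_end = _window(e.target, k)
        peak_id = f"peak_{len(peaks):05d}"
        peaks.append((peak_id, chrom, w_start, w_end))
        consensus = "".join(BASES[np.argmax(pwms[e.regulator], axis=0)])
        strand = "+" if rng.random() < 0.5 else "-"
        planted = consensus if strand == "+" else reverse_complement(consensus)
        offset = PEAK_LEN // 2 - PWM_LEN // 2
        pos = w_start + offset
        seq[pos:pos + PWM_LEN] = [int(np.where(BASES == b)[0][0]) for b in planted]
        placements.append((e.regulator, e.target, peak_id, offset, strand))

    # one motif-free background peak per gene, inside the gene body's far end
    for row in genes.itertuples():
        peak_id = f"peak_{len(peaks):05d}"
        if row.strand == "+":
            b_start = row.end - PEAK_LEN - 100
        else:
            b_start = row.start + 100
        peaks.append((peak_id, row.chrom, int(b_start), int(b_start) + PEAK_LEN))

    sequences = {chrom: "".join(BASES[seq])}
    return ToyGenome(
        genes=genes,
        sequences=sequences,
        pwms=pwms,
        peaks=pd.DataFrame(peaks, columns=["peak_id", "chrom", "start", "end"]),
        placements=pd.DataFrame(
            placements, columns=["regulator", "target", "peak_id", "offset", "strand"]),
    )


# ---------------------------------------------------------------------------
# Expression / accessibility time course
# ---------------------------------------------------------------------------

def _pattern_profile(pattern: str, n_post: int, fold: float) -> np.ndarray:
    """Fold-change profile over post-baseline timepoints for an archetype."""
    prof = np.ones(n_post)
    if pattern == "early-up":
        prof[:] = fold
    elif pattern == "late-up":
        onset = -(-n_post // 2)  # ceil: second half of the time course
        prof[onset:] = fold
    elif pattern == "up-then-down":
        prof[: min(2, n_post)] = fold
    elif pattern == "flat":
        pass
    else:
        raise ValueError(f"unknown pattern {pattern!r}")
    return prof


def expression_means(truth: GroundTruth, config: SyntheticConfig,
                     base_mean: float = 200.0, fold: float = 4.0) -> pd.DataFrame:
    """Planted per-TF NB mean profiles (genes x timepoints).

    Cluster archetypes set the backbone; planted edges then force the
    regulator up from the timepoint preceding the onset and the target
    changed in the edge's direction from the onset onward, so that every
    planted edge satisfies the expression criteria of network inference.
    """
    tps = config.timepoints
    n_post = len(tps) - 1
    tfs = tf_symbols(config.n_tf)
    prof = {tf: np.ones(n_post) for tf in tfs}

    for tf, pattern in truth.planted_cluster.items():
        prof[tf] = _pattern_profile(pattern, n_post, fold)
    for tf in ("NEUROG1", "NEUROG2"):
        if tf in prof:
            prof[tf] = np.maximum(prof[tf], fold)  # dox-induced throughout

    post_index = {tp: i for i, tp in enumerate(tps[1:])}
    for e in truth.planted_edges:
        j = post_index[e.onset]
        if j > 0:
            prof[e.regulator][j - 1:] = np.maximum(prof[e.regulator][j - 1:], fold)
        if e.sign == ACTIVATING:
            prof[e.target][j:] = np.maximum(prof[e.target][j:], fold)
        else:
            prof[e.target][j:] = np.minimum(prof[e.target][j:], 1.0 / fold)

    mat = np.ones((len(tfs), len(tps)))
    for i, tf in enumerate(tfs):
        mat[i, 1:] = prof[tf]
    return pd.DataFrame(mat * base_mean, index=tfs, columns=list(tps))


def _nb_draw(rng: np.random.Generator, mean: np.ndarray,
             dispersion: float) -> np.ndarray:
    """NB counts with variance mu + dispersion * mu^2 (size = 1/dispersion)."""
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    size = 1.0 / dispersion
    mean = np.asarray(mean, dtype=float)
    p = size / (size + np.maximum(mean, 1e-12))
    return rng.negative_binomial(size, p)


def simulate_timecourse(
    truth: GroundTruth,
    genome: ToyGenome,
    config: SyntheticConfig,
    base_mean: float = 200.0,
    fold: float = 4.0,
    atac_on_mean: float = 100.0,
    atac_off_mean: float = 5.0,
    peak_scale: Mapping[str, float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate expression and ATAC counts consistent with the planted network.

    Returns ``(expression, expr_samples, atac)``: a genes x samples count
    matrix, its sample sheet (sample, timepoint, replicate), and a peaks x
    samples ATAC count matrix whose columns are ``<tp>_a<rep>``.  Peaks
    carrying a planted motif for edge R->T switch from ``atac_off_mean`` to
    ``atac_on_mean`` per replicate at the edge's onset, so the summed pair
    reads exceed the 50-read floor and the ESC baseline exactly when the edge
    is active; background peaks stay low everywhere.  ``peak_scale`` can
    scale accessible-peak means per regulator (used to plant cluster-specific
    accessibility differences).
    """
    tps = config.timepoints
    rng = np.random.default_rng([config.seed, 23])
    means = expression_means(truth, config, base_mean=base_mean, fold=fold)

    cols, meta = [], []
    expr = np.zeros((means.shape[0], len(tps) * config.n_replicates), dtype=np.int64)
    j = 0
    for tp in tps:
        for r in range(1, config.n_replicates + 1):
            expr[:, j] = _nb_draw(rng, means[tp].to_numpy(), config.dispersion)
            cols.append(f"{tp}_r{r}")
            meta.append((f"{tp}_r{r}", tp, r))
            j += 1
    expression = pd.DataFrame(expr, index=means.index, columns=cols)
    expr_samples = pd.DataFrame(meta, columns=["sample", "timepoint", "replicate"])

    onset_ix = {tp: i for i, tp in enumerate(tps)}
    placement_onset = {}
    for e in truth.planted_edges:
        for row in genome.placements.itertuples():
            if row.regulator == e.regulator and row.target == e.target:
                placement_onset[row.peak_id] = (onset_ix[e.onset], e.regulator)

    scale = dict(peak_scale or {})
    peak_ids = genome.peaks["peak_id"].to_numpy()
    atac_cols = [f"{tp}_a{r}" for tp in tps for r in range(1, config.n_atac_replicates + 1)]
    atac = np.zeros((len(peak_ids), len(atac_cols)), dtype=np.int64)
    for i, pid in enumerate(peak_ids):
        onset, reg = placement_onset.get(pid, (None, None))
        j = 0
        for t, tp in enumerate(tps):
            on = onset is not None and t >= onset
            mu = atac_on_mean * scale.get(reg, 1.0) if on else atac_off_mean
            for _ in range(config.n_atac_replicates):
                atac[i, j] = _nb_draw(rng, np.array([mu]), config.dispersion)[0]
                j += 1
    atac_counts = pd.DataFrame(atac, index=peak_ids, columns=atac_cols)
    return expression, expr_samples, atac_counts


def atac_sample_sheet(config: SyntheticConfig) -> pd.DataFrame:
    rows = [(f"{tp}_a{r}", tp, r)
            for tp in config.timepoints
            for r in range(1, config.n_atac_replicates + 1)]
    return pd.DataFrame(rows, columns=["sample", "timepoint", "replicate"])


def plant_hierarchy(
    config: SyntheticConfig,
    n_a: int = 3,
    targets_per_a: int = 2,
    n_repressed: int = 1,
    n_c: int = 2,
) -> GroundTruth:
    """A planted regulator hierarchy: seeds -> cluster-A TFs -> B/C targets.

    NEUROG1/2 activate ``n_a`` early TFs at the first post-baseline timepoint;
    each early TF then regulates ``targets_per_a`` later TFs (the last
    ``n_repressed`` of them repressed) at subsequent timepoints.  Early TFs
    are labelled 'early-up', activated targets 'late-up', plus ``n_c``
    standalone 'up-then-down' TFs and the remainder 'flat'.
    """
    tfs = tf_symbols(config.n_tf)
    others = [t for t in tfs if not t.startswith("NEUROG")]
    need = n_a + n_a * targets_per_a + n_c
    if need > len(others):
        raise ValueError("not enough TFs for the requested hierarchy")
    a_tfs = others[:n_a]
    targets = others[n_a:n_a + n_a * targets_per_a]
    c_tfs = others[n_a + n_a * targets_per_a:need]
    post = config.timepoints[1:]
    if len(post) < 2:
        raise ValueError("hierarchy needs at least two post-baseline timepoints")

    edges = []
    for a in a_tfs:
        edges.append(PlantedEdge("NEUROG1", a, post[0], ACTIVATING))
        edges.append(PlantedEdge("NEUROG2", a, post[0], ACTIVATING))
    for i, a in enumerate(a_tfs):
        mine = targets[i * targets_per_a:(i + 1) * targets_per_a]
        for j, t in enumerate(mine):
            onset = post[1 + (i + j) % (len(post) - 1)]
            sign = REPRESSING if j >= targets_per_a - n_repressed else ACTIVATING
            edges.append(PlantedEdge(a, t, onset, sign))

    cluster = {a: "early-up" for a in a_tfs}
    for e in edges:
        if e.sign == ACTIVATING and e.regulator in a_tfs:
            cluster[e.target] = "late-up"
    cluster.update({c: "up-then-down" for c in c_tfs})
    edge_targets = {e.target for e in edges}
    flat = [t for t in others if t not in cluster and t not in edge_targets]
    cluster.update({t: "flat" for t in flat})
    return GroundTruth(planted_edges=tuple(edges), planted_cluster=cluster)


# ---------------------------------------------------------------------------
# Plain-text writers (TSV / BED / FASTA / JASPAR / narrowPeak)
# ---------------------------------------------------------------------------

def write_manifest(manifest: pd.DataFrame, path) -> None:
    manifest.to_csv(path, sep="\t", index=False)


def write_counts(counts: pd.DataFrame, path, index_label: str = "guide_id") -> None:
    counts.to_csv(path, sep="\t", index_label=index_label)


def write_gene_models_bed(genes: pd.DataFrame, path) -> None:
    """Gene bodies as BED6 (name = gene symbol, score = 0)."""
    bed = genes[["chrom", "start", "end", "gene"]].copy()
    bed["score"] = 0
    bed["strand"] = genes["strand"].to_numpy()
    bed.to_csv(path, sep="\t", header=False, index=False)


def write_genome_fasta(sequences: Mapping[str, str], path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    seqio_write(records, path, "fasta")


def write_pfms_jaspar(pwms: Mapping[str, np.ndarray], path, scale: int = 100) -> None:
    """PWMs as JASPAR-style 4-row position-frequency matrices."""
    from Bio import motifs as bio_motifs
    from Bio.motifs import jaspar as bio_jaspar

    records = []
    for name, mat in pwms.items():
        counts = {b: (mat[i] * scale).round().astype(int).tolist()
                  for i, b in enumerate("ACGT")}
        m = bio_motifs.Motif(alphabet="ACGT", counts=counts)
        m.matrix_id = name
        m.name = name
        records.append(m)
    text = bio_jaspar.write(records, "jaspar")
    with open(path, "w") as fh:
        fh.write(text)


def write_narrowpeak(peaks: pd.DataFrame, path) -> None:
    np_df = peaks[["chrom", "start", "end", "peak_id"]].copy()
    np_df["score"] = 0
    np_df["strand"] = "."
    np_df["signalValue"] = 0.0
    np_df["pValue"] = -1.0
    np_df["qValue"] = -1.0
    np_df["peak"] = -1
    np_df.to_csv(path, sep="\t", header=False, index=False)


def write_sample_sheet(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t", index=False)
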