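"""Synthetic small RNA-seq experiment generator.

Emits a toy genome with non-overlapping annotation tracks (miRNA loci,
piRNA clusters, tRNA genes, repeat elements, exons, plus unannotated
"background" loci), and per-sample collections of already-aligned reads
(BED6 coordinates + sequence) whose statistical structure matches what
the downstream analysis assumes about testis small RNA populations:

* three read-length peaks at 22 nt (miRNA), 30 nt (piRNA/repeat) and
  33 nt (tRNA halves), plus a ~20 nt tRF population;
* ~70 % 5'-uridine and elevated position-10 adenine in piRNA-class reads
  of normal samples (the ping-pong signature), decaying to the 25 %
  random baseline in tumor samples;
* 5'-guanine enrichment in 32-34 nt reads;
* tRNA-derived reads anchored at the 5' end of their tRNA gene;
* global tumor piRNA loss (default log2 fold change -5), partial repeat
  loss, a designated strongly up-regulated miRNA subset (default 23
  features at log2FC +11) and a small down-regulated tRF subset;
* negative-binomial count noise around group means, with a configurable
  fraction of multi-mapping piRNA reads.

Counts are generated feature-by-feature: per-group expected means are
derived from class mixture weights, per-feature expression weights and
the injected fold changes, then per-sample counts are drawn NB(mean,
dispersion) and that many reads are emitted from the feature.  The
ground-truth table records every feature's class, group means and true
log2 fold change, so parameter-recovery tests can compare pipeline
output against what was injected.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: read classes in a fixed order (mixture weights are defined over these)
CLASSES = ("miRNA", "piRNA", "tRNA_half", "tRF", "repeat", "exon", "other")

#: annotation track feeding each read class
CLASS_TRACK = {
    "miRNA": "mirna",
    "piRNA": "pirna_cluster",
    "tRNA_half": "trna",
    "tRF": "trna",
    "repeat": "repeat",
    "exon": "exon",
    "other": "unannotated",
}

#: tracks written as BED annotation (unannotated loci are truth-only)
ANNOTATION_TRACKS = ("mirna", "pirna_cluster", "trna", "repeat", "exon")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_A, _C, _G, _T = 0, 1, 2, 3


class PlacementError(RuntimeError):
    """Requested features cannot be placed without forbidden overlap."""


class ConfigurationError(ValueError):
    """Simulation parameters are inconsistent with the genome/tracks."""


# --------------------------------------------------------------------------
# genome + annotation
# --------------------------------------------------------------------------

@dataclass
class GenomeSpec:
    """Layout of the toy genome and its annotation tracks."""

    n_chromosomes: int = 3
    chrom_length: int = 2_000_000
    n_mirna_loci: int = 60
    n_pirna_clusters: int = 114
    n_trna_genes: int = 500
    n_repeat_elements: int = 60
    n_exons: int = 200
    n_unannotated: int = 80
    seed: int = 0

    def validate(self) -> None:
        counts = [self.n_chromosomes, self.chrom_length, self.n_mirna_loci,
                  self.n_pirna_clusters, self.n_trna_genes,
                  self.n_repeat_elements, self.n_exons, self.n_unannotated]
        if any(c < 0 for c in counts):
            raise ValueError("all GenomeSpec counts must be >= 0")
        if self.n_chromosomes == 0 or self.chrom_length <= 0:
            raise ValueError("need at least one chromosome of positive length")


#: (track, count attribute, feature width sampler bounds)
_TRACK_LAYOUT = [
    ("pirna_cluster", "n_pirna_clusters", (1_000, 5_000)),
    ("repeat", "n_repeat_elements", (200, 400)),
    ("exon", "n_exons", (150, 300)),
    ("unannotated", "n_unannotated", (400, 600)),
    ("trna", "n_trna_genes", (72, 73)),
    ("mirna", "n_mirna_loci", (22, 23)),
]

#: spacer kept between placed features so reads from adjacent features
#: can never merge into one contig: larger than the default contig gap
#: tolerance (100 bp) plus the maximum read length (36 nt)
_PLACEMENT_MARGIN = 150


def make_genome(spec: GenomeSpec) -> tuple[dict[str, str], dict[str, pd.DataFrame]]:
    """Generate random chromosome sequences and non-overlapping tracks.

    Returns ``(genome, tracks)`` where genome maps chromosome name to its
    sequence and tracks maps track name (``mirna``, ``pirna_cluster``,
    ``trna``, ``repeat``, ``exon``, ``unannotated``) to a BED6 DataFrame.
    Deterministic under ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    chroms = [f"chr{i + 1}" for i in range(spec.n_chromosomes)]
    genome = {
        c: _BASES[rng.integers(0, 4, spec.chrom_length)].tobytes().decode("ascii")
        for c in chroms
    }

    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    tracks: dict[str, pd.DataFrame] = {}
    for track, attr, (wlo, whi) in _TRACK_LAYOUT:
        n = getattr(spec, attr)
        rows = []
        for i in range(n):
            width = int(rng.integers(wlo, whi))
            placed = False
            for _ in range(2_000):
                chrom = chroms[int(rng.integers(len(chroms)))]
                if spec.chrom_length <= width:
                    break
                start = int(rng.integers(0, spec.chrom_length - width))
                end = start + width
                lo = start - _PLACEMENT_MARGIN
                hi = end + _PLACEMENT_MARGIN
                if all(e <= lo or s >= hi for s, e in occupied[chrom]):
                    occupied[chrom].append((start, end))
                    placed = True
                    break
            if not placed:
                raise PlacementError(
                    f"could not place {track} feature {i} without overlap; "
                    "reduce feature counts or enlarge the genome"
                )
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append((chrom, start, end, f"{track}_{i:04d}", 0, strand))
        tracks[track] = pd.DataFrame(
            rows, columns=["chrom", "start", "end", "name", "score", "strand"]
        ).sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    return genome, tracks


# --------------------------------------------------------------------------
# group parameters
# --------------------------------------------------------------------------

def _default_length_models() -> dict[str, tuple[np.ndarray, np.ndarray]]:
    def model(lo, hi, probs):
        p = np.asarray(probs, dtype=float)
        return np.arange(lo, hi + 1), p / p.sum()

    pirna = model(24, 31, [0.02, 0.03, 0.04, 0.06, 0.10, 0.18, 0.44, 0.13])
    return {
        "miRNA": model(20, 24, [0.05, 0.20, 0.50, 0.20, 0.05]),
        "piRNA": pirna,
        "repeat": pirna,
        "tRNA_half": model(32, 36, [0.15, 0.45, 0.20, 0.12, 0.08]),
        "tRF": model(18, 24, [0.06, 0.12, 0.38, 0.22, 0.12, 0.06, 0.04]),
        "exon": model(19, 30, [1] * 12),
        "other": model(24, 36, [1] * 13),
    }


def _default_class_weights() -> dict[str, float]:
    return {
        "miRNA": 0.18,
        "piRNA": 0.22,
        "tRNA_half": 0.27,
        "tRF": 0.08,
        "repeat": 0.12,
        "exon": 0.05,
        "other": 0.08,
    }


@dataclass
class GroupParams:
    """Per-group generative parameters.

    ``class_weights`` are the expected read-mass proportions per class in
    the *normal* reference condition; tumor-group masses are derived from
    them by applying the injected fold changes (so a tumor sample's total
    expected depth is lower than ``depth`` when piRNAs are lost).
    """

    group_label: str = "normal"
    class_weights: dict[str, float] = field(default_factory=_default_class_weights)
    length_models: dict[str, tuple[np.ndarray, np.ndarray]] = field(
        default_factory=_default_length_models)
    p_5primeU_piRNA: float = 0.70
    p_10A_piRNA: float = 0.35
    p_5primeG_32_34: float = 0.55
    pirna_log2fc_tumor: float = -5.0
    repeat_log2fc_tumor: float = -2.5
    mirna_up_n: int = 23
    mirna_up_log2fc: float = 11.0
    mirna_up_base_mean: float = 1.0   # expected normal counts per up-feature
    #                                   per 1e5 reads of depth
    trf_down_n: int = 3
    trf_down_log2fc: float = -2.5
    dispersion: float = 0.05
    depth: float = 100_000.0
    multimap_fraction: float = 0.10
    multimap_max: int = 4
    trna_5prime_prob: float = 0.90
    cis_mix: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        total = sum(self.class_weights.get(c, 0.0) for c in CLASSES)
        if not np.isclose(total, 1.0, atol=1e-6):
            raise ValueError(f"class_weights must sum to 1 (got {total})")
        for p in (self.p_5primeU_piRNA, self.p_10A_piRNA, self.p_5primeG_32_34,
                  self.multimap_fraction, self.trna_5prime_prob, self.cis_mix):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")


def normal_params(**overrides) -> GroupParams:
    return replace(GroupParams(), group_label="normal", **overrides)


def tumor_params(base: GroupParams | None = None, group_label: str = "tumor",
                 **overrides) -> GroupParams:
    """Tumor-group parameters: random base composition at positions 1/10
    (piRNA pathway lost), same fold-change bookkeeping as the base."""
    base = base if base is not None else GroupParams()
    return replace(base, group_label=group_label, p_5primeU_piRNA=0.25,
                   p_10A_piRNA=0.25, **overrides)


def cis_params(base: GroupParams | None = None, mix: float | None = None,
               **overrides) -> GroupParams:
    """CIS as a transitional state: signature probabilities interpolated
    between the normal and tumor (= random) values at ``cis_mix``."""
    base = base if base is not None else GroupParams()
    f = base.cis_mix if mix is None else mix
    return replace(
        base, group_label="CIS",
        p_5primeU_piRNA=(1 - f) * base.p_5primeU_piRNA + f * 0.25,
        p_10A_piRNA=(1 - f) * base.p_10A_piRNA + f * 0.25,
        cis_mix=f, **overrides)


def default_params_by_group(groups, base: GroupParams | None = None
                            ) -> dict[str, GroupParams]:
    base = base if base is not None else GroupParams()
    out = {}
    for g in groups:
        if g == "normal":
            out[g] = replace(base, group_label="normal")
        elif g == "CIS":
            out[g] = cis_params(base)
        else:
            out[g] = tumor_params(base, group_label=g)
    return out


def default_design(n_normal: int = 12, n_tumor: int = 10, n_cis: int = 0,
                   tumor_label: str = "tumor") -> pd.DataFrame:
    """Sample table: normal samples are controls, CIS and tumor are cases
    (CIS lesions are grouped with the tumors in the case/control contrast)."""
    rows = []
    for i in range(n_normal):
        rows.append((f"normal_{i + 1:02d}", "normal", "control"))
    for i in range(n_cis):
        rows.append((f"CIS_{i + 1:02d}", "CIS", "case"))
    for i in range(n_tumor):
        rows.append((f"{tumor_label}_{i + 1:02d}", tumor_label, "case"))
    return pd.DataFrame(rows, columns=["sample_id", "group", "condition"])


# --------------------------------------------------------------------------
# ground truth
# --------------------------------------------------------------------------

def build_truth(tracks: dict[str, pd.DataFrame], params: GroupParams,
                seed: int | None = None) -> pd.DataFrame:
    """Per-feature truth table: class, normal/tumor expected mean counts
    and true log2 fold change (tumor vs normal).

    Expression mass within each class is spread over the class's features
    with log-normal weights (sigma = 1), a realistic right-skewed
    expression profile.  The designated miRNA up-subset instead gets a
    fixed small normal-group baseline so that its +11 log2FC is resolvable
    at the default depth.
    """
    params.validate()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    frames = []
    for klass in CLASSES:
        track = tracks.get(CLASS_TRACK[klass])
        weight = params.class_weights.get(klass, 0.0)
        if weight <= 0:
            continue
        if track is None or len(track) == 0:
            raise ConfigurationError(
                f"class {klass!r} has weight {weight} but its annotation "
                f"track ({CLASS_TRACK[klass]!r}) is empty")
        feats = track.copy()
        feats["feature_id"] = klass + "@" + feats["name"]
        feats["klass"] = klass
        mass = weight * params.depth
        w = rng.lognormal(0.0, 1.0, len(feats))
        mean_normal = mass * w / w.sum()
        mean_tumor = mean_normal.copy()

        if klass == "miRNA" and params.mirna_up_n > 0:
            n_up = min(params.mirna_up_n, len(feats))
            base = params.mirna_up_base_mean * params.depth / 1e5
            up = np.zeros(len(feats), dtype=bool)
            up[:n_up] = True
            rest_mass = max(mass - base * n_up, 0.0)
            mean_normal[up] = base
            mean_normal[~up] = rest_mass * w[~up] / w[~up].sum() if (~up).any() else 0.0
            mean_tumor = mean_normal.copy()
            mean_tumor[up] = base * 2.0 ** params.mirna_up_log2fc
            feats["is_up_mirna"] = up
        elif klass in ("piRNA", "repeat"):
            lfc = (params.pirna_log2fc_tumor if klass == "piRNA"
                   else params.repeat_log2fc_tumor)
            mean_tumor = mean_normal * 2.0 ** lfc
        elif klass == "tRF" and params.trf_down_n > 0:
            n_down = min(params.trf_down_n, len(feats))
            mean_tumor = mean_normal.copy()
            mean_tumor[:n_down] *= 2.0 ** params.trf_down_log2fc
            feats["is_down_trf"] = np.zeros(len(feats), dtype=bool)
            feats.loc[feats.index[:n_down], "is_down_trf"] = True

        feats["mean_normal"] = mean_normal
        feats["mean_tumor"] = mean_tumor
        frames.append(feats)

    truth = pd.concat(frames, ignore_index=True)
    for col in ("is_up_mirna", "is_down_trf"):
        if col in truth:
            truth[col] = truth[col].notna() & truth[col].eq(True)
        else:
            truth[col] = False
    with np.errstate(divide="ignore", invalid="ignore"):
        truth["log2fc_true"] = np.log2(truth["mean_tumor"] / truth["mean_normal"])
    cols = ["feature_id", "klass", "chrom", "start", "end", "strand", "name",
            "mean_normal", "mean_tumor", "log2fc_true", "is_up_mirna",
            "is_down_trf"]
    return truth[cols]


def group_means(truth: pd.DataFrame, group_label: str,
                cis_mix: float = 0.5) -> np.ndarray:
    """Expected per-feature counts for a group.  CIS is a linear cell
    mixture of the normal and tumor expectations."""
    if group_label == "normal":
        return truth["mean_normal"].to_numpy(float)
    if group_label == "CIS":
        return ((1 - cis_mix) * truth["mean_normal"].to_numpy(float)
                + cis_mix * truth["mean_tumor"].to_numpy(float))
    return truth["mean_tumor"].to_numpy(float)


# --------------------------------------------------------------------------
# read emission
# --------------------------------------------------------------------------

def _draw_counts(rng: np.random.Generator, means: np.ndarray,
                 dispersion: float) -> np.ndarray:
    """NB(mean, alpha) counts; alpha = 0 is the Poisson limit."""
    means = np.asarray(means, dtype=float)
    if dispersion <= 0:
        return rng.poisson(means)
    size = 1.0 / dispersion
    p = size / (size + means)
    return rng.negative_binomial(size, p)


def _force_position(rng, mat, col, mask, base_idx, prob):
    """Set column `col` to `base_idx` with probability `prob` on `mask`
    rows, else draw uniformly from the other three bases (so the marginal
    frequency of `base_idx` is exactly `prob`)."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return
    hit = rng.random(idx.size) < prob
    mat[idx[hit], col] = base_idx
    others = np.delete(np.arange(4), base_idx)
    mat[idx[~hit], col] = rng.choice(others, size=(~hit).sum())


def _sequences(rng, lengths, klass, params: GroupParams) -> np.ndarray:
    """Random sequences (DNA alphabet) with the class/length positional
    biases applied; returns an object array of strings."""
    out = np.empty(lengths.size, dtype=object)
    for L in np.unique(lengths):
        rows = np.flatnonzero(lengths == L)
        mat = rng.integers(0, 4, size=(rows.size, int(L)), dtype=np.int64)
        all_rows = np.ones(rows.size, dtype=bool)
        if klass in ("piRNA", "repeat"):
            _force_position(rng, mat, 0, all_rows, _T, params.p_5primeU_piRNA)
            if L >= 10:
                _force_position(rng, mat, 9, all_rows, _A, params.p_10A_piRNA)
        elif 32 <= L <= 34:
            _force_position(rng, mat, 0, all_rows, _G, params.p_5primeG_32_34)
        seqs = _BASES[mat].view(f"S{int(L)}").ravel()
        out[rows] = seqs.astype(str)
    return out


def simulate_sample(genome: dict[str, str], tracks: dict[str, pd.DataFrame],
                    params: GroupParams, seed: int,
                    feature_means: pd.DataFrame | None = None,
                    sample_id: str = "sample") -> pd.DataFrame:
    """Emit one sample's aligned reads as a BED6+sequence DataFrame.

    ``feature_means`` is a truth table (from :func:`build_truth`) with a
    ``mean`` column giving this sample's expected per-feature counts;
    when omitted it is derived from ``params.class_weights`` directly
    (normal-style expression, no fold changes).  Read names encode the
    generating truth feature (``<feature_id>:<i>``), and multi-mapped
    piRNA reads emit extra alignment records with identical name and
    sequence at other piRNA clusters.
    """
    rng = np.random.default_rng(seed)
    if feature_means is None:
        truth = build_truth(tracks, params)
        truth["mean"] = group_means(truth, params.group_label, params.cis_mix)
    else:
        truth = feature_means
    counts = _draw_counts(rng, truth["mean"].to_numpy(float), params.dispersion)

    chrom_arr = truth["chrom"].to_numpy()
    start_arr = truth["start"].to_numpy()
    end_arr = truth["end"].to_numpy()
    strand_arr = truth["strand"].to_numpy()
    fid_arr = truth["feature_id"].to_numpy()
    klass_arr = truth["klass"].to_numpy()

    frames = []
    for klass in CLASSES:
        sel = np.flatnonzero((klass_arr == klass) & (counts > 0))
        if sel.size == 0:
            continue
        n = counts[sel]
        fi = np.repeat(sel, n)
        total = fi.size
        lens_model, probs = params.length_models[klass]
        lengths = rng.choice(lens_model, size=total, p=probs)

        fstart = start_arr[fi]
        fend = end_arr[fi]
        fstrand = strand_arr[fi]
        if klass in ("tRF", "tRNA_half"):
            at5 = rng.random(total) < params.trna_5prime_prob
            offset = np.where(at5, 0, rng.integers(3, 20, total))
            plus = fstrand == "+"
            start = np.where(plus, fstart + offset, fend - offset - lengths)
            start = np.maximum(start, fstart)
        else:
            span = np.maximum(fend - fstart - lengths, 0)
            start = fstart + (rng.random(total) * (span + 1)).astype(np.int64)
        end = start + lengths

        seqs = _sequences(rng, lengths, klass, params)
        names = np.char.add(np.char.add(fid_arr[fi].astype(str), ":"),
                            np.arange(total).astype(str))
        df = pd.DataFrame({
            "chrom": chrom_arr[fi], "start": start, "end": end,
            "name": names, "score": 0, "strand": fstrand, "seq": seqs,
        })

        if klass == "piRNA" and params.multimap_fraction > 0:
            clusters = tracks.get("pirna_cluster")
            if clusters is not None and len(clusters) > 1:
                mm = np.flatnonzero(rng.random(total) < params.multimap_fraction)
                if mm.size:
                    k_extra = rng.integers(
                        1, min(params.multimap_max, 100), mm.size)
                    rep = np.repeat(mm, k_extra)
                    tgt = rng.integers(0, len(clusters), rep.size)
                    cst = clusters["start"].to_numpy()[tgt]
                    cen = clusters["end"].to_numpy()[tgt]
                    L = lengths[rep]
                    span = np.maximum(cen - cst - L, 0)
                    nstart = cst + (rng.random(rep.size) * (span + 1)).astype(np.int64)
                    extra = pd.DataFrame({
                        "chrom": clusters["chrom"].to_numpy()[tgt],
                        "start": nstart, "end": nstart + L,
                        "name": df["name"].to_numpy()[rep], "score": 0,
                        "strand": clusters["strand"].to_numpy()[tgt],
                        "seq": df["seq"].to_numpy()[rep],
                    })
                    df = pd.concat([df, extra], ignore_index=True)
        frames.append(df)

    if not frames:
        return pd.DataFrame(columns=["chrom", "start", "end", "name",
                                     "score", "strand", "seq"])
    reads = pd.concat(frames, ignore_index=True)
    reads = reads.sort_values(["chrom", "start", "end", "name"],
                              kind="stable").reset_index(drop=True)
    return reads


def simulate_experiment(genome: dict[str, str], tracks: dict[str, pd.DataFrame],
                        design: pd.DataFrame,
                        params_by_group: dict[str, GroupParams] | None = None,
                        seed: int = 0,
                        ) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Simulate every sample in the design table.

    Returns ``(reads_by_sample, truth)``.  A single truth table (drawn
    from ``seed``) is shared by all samples, so per-feature expression
    weights are common across groups and only the injected fold changes
    differentiate them.  Per-sample read noise uses independent child
    seeds spawned from ``seed``.
    """
    import warnings

    groups = list(dict.fromkeys(design["group"]))
    if params_by_group is None:
        params_by_group = default_params_by_group(groups)
    base = params_by_group.get("normal", next(iter(params_by_group.values())))
    truth = build_truth(tracks, base, seed=seed)

    for cond in ("case", "control"):
        if (design["condition"] == cond).sum() < 2:
            warnings.warn(
                f"fewer than 2 {cond!r} samples: downstream differential "
                "expression will be underpowered", stacklevel=2)

    child_seeds = np.random.SeedSequence(seed).spawn(len(design))
    reads_by_sample: dict[str, pd.DataFrame] = {}
    for (row, ss) in zip(design.itertuples(index=False), child_seeds):
        params = params_by_group[row.group]
        means = truth.copy()
        means["mean"] = group_means(truth, row.group, params.cis_mix)
        sample_seed = ss.generate_state(1)[0]
        reads_by_sample[row.sample_id] = simulate_sample(
            genome, tracks, params, int(sample_seed), feature_means=means,
            sample_id=row.sample_id)
    return reads_by_sample, truth
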