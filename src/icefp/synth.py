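"""Synthetic communities, electropherograms and clone libraries.

The generator plants the latent structure the downstream analysis assumes
for an over-wintering sea-ice microbial community:

* a set of "core" OTUs present in every sample, carrying a configured
  fraction of the total fingerprint signal, with skewed (geometric-profile,
  lognormal-dispersed) abundances;
* "transient" OTUs that occur independently per sample with a fixed
  presence probability;
* forward-modelled electropherograms — one Gaussian peak per OTU over i.i.d.
  Gaussian baseline noise, clipped at a detector ceiling, with a constant
  migration (dye) offset between the sample and ladder channels;
* clone libraries drawn multinomially from the same community, with
  phylotype-structured gene sequences and ITS-length (or restriction-site)
  subtypes so that fingerprint fragment lengths are predictable in silico.

Everything is driven by a single integer seed and is bit-reproducible.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .trace import Trace

__all__ = [
    "OTUSpec",
    "CommunityModel",
    "SynthTraceConfig",
    "PhylotypeSpec",
    "CloneSequence",
    "simulate_community",
    "render_trace",
    "render_ladder",
    "sample_clone_library",
    "arisa_community",
    "trflp_community",
    "ARISA_TRACE_CONFIG",
    "TRFLP_TRACE_CONFIG",
    "FORWARD_PRIMER",
    "REVERSE_PRIMER",
    "write_clones_fasta",
    "read_clones_fasta",
]


@dataclass(frozen=True)
class OTUSpec:
    """One planted community member."""

    fragment_length: float  # bp, true (ladder-dye) length
    mean_abundance: float  # mean relative signal contribution
    is_core: bool


@dataclass
class CommunityModel:
    """Latent community: who is there and how abundant, on average.

    ``mean_abundance`` values sum to 1 across all OTUs. Transient OTUs occur
    per sample with ``transient_presence_prob``; when present their height is
    drawn around ``mean_abundance / transient_presence_prob`` so the expected
    share of signal carried by core OTUs still equals
    ``core_signal_fraction``. Per-OTU multiplicative noise is lognormal with
    sigma ``abundance_dispersion`` (mean-one parameterisation).
    """

    otus: list[OTUSpec]
    n_samples: int
    core_signal_fraction: float
    transient_presence_prob: float
    abundance_dispersion: float
    seed: int
    allow_length_collisions: bool = False

    def __post_init__(self) -> None:
        total = sum(o.mean_abundance for o in self.otus)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"CommunityModel.otus: mean abundances sum to {total!r}, "
                "must sum to 1 within 1e-9"
            )
        for o in self.otus:
            if not 70 <= o.fragment_length <= 1500:
                raise ValueError(
                    f"CommunityModel.otus: fragment length {o.fragment_length}"
                    " outside [70, 1500] bp"
                )
        if not 0 <= self.transient_presence_prob <= 1:
            raise ValueError(
                "CommunityModel.transient_presence_prob must be in [0, 1]"
            )
        if self.abundance_dispersion < 0:
            raise ValueError("CommunityModel.abundance_dispersion must be >= 0")
        if not self.allow_length_collisions:
            from .binning import bin_cutoff_for_length

            lengths = sorted(o.fragment_length for o in self.otus)
            for a, b in zip(lengths, lengths[1:]):
                if b - a <= bin_cutoff_for_length(a):
                    raise ValueError(
                        f"CommunityModel.otus: fragment lengths {a} and {b} "
                        "collide within the bin cut-off at their size"
                    )

    @property
    def core_indices(self) -> list[int]:
        return [i for i, o in enumerate(self.otus) if o.is_core]

    @property
    def fragment_lengths(self) -> np.ndarray:
        return np.array([o.fragment_length for o in self.otus])


@dataclass(frozen=True)
class SynthTraceConfig:
    """Forward model of the capillary instrument."""

    scans_per_bp: float = 10.0
    peak_sigma: float = 10.0  # scan units (= 1 bp at default resolution)
    baseline_noise_rms: float = 30.0  # RFU
    saturation_ceiling: float | None = 65535.0  # 16-bit detector
    signal_scale: float = 1.0e5  # RFU carried by unit total abundance
    dye_offset_bp: float = 7.0  # sample dye runs +7 bp vs the ladder dye
    ladder_lengths: tuple[float, ...] = tuple(
        float(x)
        for x in (75, 100, 150, 200, 250, 300, 350, 400, 450, 500, 550, 600,
                  700, 800, 900, 1000, 1100, 1200, 1300, 1400, 1500)
    )
    ladder_peak_height: float = 5000.0  # RFU
    origin_bp: float = 50.0  # bp at scan 0
    span_bp: float = 1500.0  # trace covers [origin, origin + span] bp

    def __post_init__(self) -> None:
        if self.peak_sigma <= 0:
            raise ValueError("peak_sigma must be positive")
        if self.saturation_ceiling is not None and self.saturation_ceiling <= 0:
            raise ValueError("saturation_ceiling must be positive")
        if any(b - a <= 0 for a, b in zip(self.ladder_lengths,
                                          self.ladder_lengths[1:])):
            raise ValueError("ladder lengths must be strictly increasing")

    @property
    def n_scans(self) -> int:
        return int(round(self.span_bp * self.scans_per_bp))

    def bp_to_scan(self, bp: float) -> float:
        return (bp - self.origin_bp) * self.scans_per_bp


ARISA_TRACE_CONFIG = SynthTraceConfig()
# Lower ceiling: the archaeal assay's strongest fragments clip, exercising
# Gaussian saturation recovery; higher total signal matches its QC cut-off.
TRFLP_TRACE_CONFIG = SynthTraceConfig(
    signal_scale=1.5e5, saturation_ceiling=30000.0,
    span_bp=800.0, ladder_lengths=tuple(
        float(x) for x in (75, 100, 150, 200, 250, 300, 350, 400, 450, 500,
                           550, 600, 700, 800)
    ),
)


def _geometric_profile(n: int, total: float, ratio: float = 0.85) -> np.ndarray:
    w = ratio ** np.arange(n)
    return total * w / w.sum()


def _spread_lengths(n: int, lo: float, hi: float) -> list[float]:
    return list(np.round(np.linspace(lo, hi, n), 1))


def arisa_community(seed: int = 0) -> CommunityModel:
    """Default bacterial ARISA study: 11 samples, 14 core OTUs at 77.5% of
    signal, 13 transients at presence probability 0.5 (mean Sørensen
    similarity to the first sample ~84%, richness ~19-24)."""
    n_core, n_trans = 14, 13
    lengths = _spread_lengths(n_core + n_trans, 420.0, 1180.0)
    core_ab = _geometric_profile(n_core, 0.775)
    trans_ab = np.full(n_trans, 0.225 / n_trans)
    otus = [
        OTUSpec(lengths[i], float(core_ab[i]), True) for i in range(n_core)
    ] + [
        OTUSpec(lengths[n_core + j], float(trans_ab[j]), False)
        for j in range(n_trans)
    ]
    return CommunityModel(
        otus=otus, n_samples=11, core_signal_fraction=0.775,
        transient_presence_prob=0.5, abundance_dispersion=0.35, seed=seed,
    )


def trflp_community(seed: int = 0) -> CommunityModel:
    """Default archaeal T-RFLP study: 21 samples, 17 core OTUs at 88% of
    signal, 20 transients at presence probability 0.45 (mean similarity to
    the first sample ~81%, richness ~22-30)."""
    n_core, n_trans = 17, 20
    lengths = _spread_lengths(n_core + n_trans, 150.0, 650.0)
    core_ab = _geometric_profile(n_core, 0.88)
    trans_ab = np.full(n_trans, 0.12 / n_trans)
    otus = [
        OTUSpec(lengths[i], float(core_ab[i]), True) for i in range(n_core)
    ] + [
        OTUSpec(lengths[n_core + j], float(trans_ab[j]), False)
        for j in range(n_trans)
    ]
    return CommunityModel(
        otus=otus, n_samples=21, core_signal_fraction=0.88,
        transient_presence_prob=0.45, abundance_dispersion=0.35, seed=seed,
    )


def _lognormal_mean_one(rng: np.random.Generator, sigma: float, size=None):
    """Multiplicative noise with expectation exactly 1."""
    if sigma == 0:
        return np.ones(size) if size is not None else 1.0
    return np.exp(rng.normal(-0.5 * sigma**2, sigma, size=size))


def simulate_community(model: CommunityModel) -> pd.DataFrame:
    """Draw the per-sample relative-height table (samples x OTUs).

    Core OTUs appear in every sample; transient OTUs are independent
    Bernoulli draws per sample. Row sums have expectation 1 but are not
    renormalised (total signal varies between samples, as in real profiles).
    """
    rng = np.random.default_rng(model.seed)
    n, m = model.n_samples, len(model.otus)
    heights = np.zeros((n, m))
    sigma = model.abundance_dispersion
    p = model.transient_presence_prob
    for j, otu in enumerate(model.otus):
        noise = _lognormal_mean_one(rng, sigma, n)
        if otu.is_core:
            heights[:, j] = otu.mean_abundance * noise
        else:
            present = rng.random(n) < p
            if p > 0:
                heights[:, j] = present * (otu.mean_abundance / p) * noise
    samples = [f"S{i+1:02d}" for i in range(n)]
    otu_ids = [f"OTU{j+1:02d}" for j in range(m)]
    return pd.DataFrame(heights, index=samples, columns=otu_ids)


def render_trace(
    sample_abundances: Sequence[float] | np.ndarray,
    fragment_lengths: Sequence[float] | np.ndarray,
    cfg: SynthTraceConfig,
    seed: int,
    sample_id: str = "synthetic",
) -> Trace:
    """Forward-model the sample-dye channel of one electropherogram.

    Each OTU becomes a Gaussian of amplitude ``abundance * signal_scale``
    centred at ``(true length + dye_offset_bp)`` in scan coordinates (the
    sample dye migrates differently from the ladder dye); i.i.d. Gaussian
    baseline noise is added and the result clipped at the detector ceiling.
    """
    abund = np.asarray(sample_abundances, dtype=float)
    lengths = np.asarray(fragment_lengths, dtype=float)
    if np.any(abund < 0):
        raise ValueError("abundances must be non-negative")
    if abund.shape != lengths.shape:
        raise ValueError("abundances and fragment lengths differ in shape")
    rng = np.random.default_rng(seed)
    n = cfg.n_scans
    signal = rng.normal(0.0, cfg.baseline_noise_rms, n)
    truncated: list[float] = []
    scan_axis = np.arange(n, dtype=float)
    for a, L in zip(abund, lengths):
        if a == 0:
            continue
        centre = cfg.bp_to_scan(L + cfg.dye_offset_bp)
        if not 0 <= centre < n:
            truncated.append(L)
        lo = max(0, int(centre - 6 * cfg.peak_sigma))
        hi = min(n, int(centre + 6 * cfg.peak_sigma) + 1)
        if lo < hi:
            signal[lo:hi] += (a * cfg.signal_scale) * np.exp(
                -0.5 * ((scan_axis[lo:hi] - centre) / cfg.peak_sigma) ** 2
            )
    meta: dict = {}
    if truncated:
        warnings.warn(
            f"{sample_id}: {len(truncated)} peak(s) outside the scan range"
        )
        meta["truncated_lengths"] = truncated
    if cfg.saturation_ceiling is not None:
        signal = np.minimum(signal, cfg.saturation_ceiling)
    return Trace(
        sample_id=sample_id, channel="sample", signal=signal,
        saturation_ceiling=cfg.saturation_ceiling, metadata=meta,
    )


def render_ladder(
    cfg: SynthTraceConfig, seed: int, sample_id: str = "synthetic"
) -> Trace:
    """Render the ladder-dye channel: size-standard peaks, no dye offset."""
    rng = np.random.default_rng(seed)
    n = cfg.n_scans
    signal = rng.normal(0.0, cfg.baseline_noise_rms, n)
    scan_axis = np.arange(n, dtype=float)
    for L in cfg.ladder_lengths:
        centre = cfg.bp_to_scan(L)
        lo = max(0, int(centre - 6 * cfg.peak_sigma))
        hi = min(n, int(centre + 6 * cfg.peak_sigma) + 1)
        if lo < hi:
            signal[lo:hi] += cfg.ladder_peak_height * np.exp(
                -0.5 * ((scan_axis[lo:hi] - centre) / cfg.peak_sigma) ** 2
            )
    if cfg.saturation_ceiling is not None:
        signal = np.minimum(signal, cfg.saturation_ceiling)
    return Trace(
        sample_id=sample_id, channel="ladder", signal=signal,
        saturation_ceiling=cfg.saturation_ceiling,
    )


# ---------------------------------------------------------------------------
# Clone libraries
# ---------------------------------------------------------------------------

#: labelled forward primer planted in every synthetic gene sequence
FORWARD_PRIMER = "GTACACACCGCCCGTCACAC"
#: reverse primer (given 5'->3' on the opposite strand)
REVERSE_PRIMER = "GGGTTTCCCCATTCGGAAAT"
#: HpyCH4III recognition site AC N GT, cut after the third base
_TRF_SITE_RE = re.compile("AC[ACGT]GT")
#: fixed ARISA amplicon overhead: forward primer + 16S tail + reverse site
_ARISA_16S_TAIL = 90


@dataclass(frozen=True)
class PhylotypeSpec:
    """Maps a phylotype to the OTU(s) whose fragment lengths are its
    subtypes. Multiple OTU indices = one 16S phylotype with several
    ITS-length (ARISA) or restriction-site (T-RFLP) variants."""

    phylotype_id: str
    otu_indices: tuple[int, ...]


@dataclass
class CloneSequence:
    """One clone: the 16S gene region plus, for ARISA-style libraries, the
    downstream spacer region through the reverse-primer site."""

    id: str
    library_id: str
    gene_region: str
    spacer_region: str = ""
    taxonomy: str | None = None
    true_phylotype: str | None = None
    true_otu: int | None = None

    def __post_init__(self) -> None:
        if not self.gene_region:
            raise ValueError("CloneSequence.gene_region must be non-empty")
        alphabet = set("ACGTN")
        if not set(self.gene_region) <= alphabet or not set(
            self.spacer_region
        ) <= alphabet:
            raise ValueError("sequences must be over {A,C,G,T,N}")

    @property
    def amplicon(self) -> str:
        return self.gene_region + self.spacer_region


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def _mutate(
    rng: np.random.Generator, seq: str, rate: float,
    protected: tuple[int, int] | None = None,
) -> str:
    """Substitute each position independently at ``rate`` (never to itself),
    leaving any protected [start, stop) interval untouched."""
    bases = "ACGT"
    chars = list(seq)
    hits = np.flatnonzero(rng.random(len(chars)) < rate)
    for i in hits:
        if protected and protected[0] <= i < protected[1]:
            continue
        alt = bases.replace(chars[i], "")
        chars[i] = alt[rng.integers(len(alt))]
    return "".join(chars)


def _scrub_trf_sites(seq: str, before: int) -> str:
    """Remove accidental restriction sites starting before ``before``."""
    chars = list(seq)
    while True:
        m = _TRF_SITE_RE.search("".join(chars[: before + 4]))
        if m is None or m.start() >= before:
            return "".join(chars)
        chars[m.start() + 1] = "G"  # break the AC..GT motif


def sample_clone_library(
    model: CommunityModel,
    n_clones: int,
    subtype_spec: Sequence[PhylotypeSpec] | None = None,
    seed: int = 0,
    assay: str = "ARISA",
    library_id: str = "LIB",
    gene_length: int = 900,
    between_phylotype_rate: float = 0.05,
    within_phylotype_rate: float = 0.002,
) -> list[CloneSequence]:
    """Draw a clone library multinomially from the community's abundances.

    Phylotype gene sequences are generated by mutating a shared ancestor at
    ``between_phylotype_rate`` per site (pairwise identity ~90%, well below
    any clustering threshold in use); within a phylotype, clones differ by
    ``within_phylotype_rate`` (identity ~99.6%, above both the bacterial 98%
    and archaeal 99% thresholds). For ARISA the spacer length is set so the
    predicted amplicon equals the OTU's fragment length; for T-RFLP a
    restriction site is planted so the terminal fragment equals it.
    """
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    if assay not in ("ARISA", "TRFLP"):
        raise ValueError(f"unknown assay {assay!r}")
    if subtype_spec is None:
        subtype_spec = [
            PhylotypeSpec(f"P{j+1:02d}", (j,)) for j in range(len(model.otus))
        ]
    n_otus = len(model.otus)
    otu_to_phylotype: dict[int, str] = {}
    for spec in subtype_spec:
        for j in spec.otu_indices:
            if not 0 <= j < n_otus:
                raise ValueError(
                    f"subtype_spec {spec.phylotype_id!r} references unknown "
                    f"OTU index {j}"
                )
            otu_to_phylotype[j] = spec.phylotype_id

    rng = np.random.default_rng(seed)
    ancestor = _random_seq(rng, gene_length)

    # one gene backbone per phylotype
    backbones: dict[str, str] = {}
    protected = None
    if assay == "ARISA":
        # keep the primer landing sites conserved
        fwd_pos = gene_length - _ARISA_16S_TAIL - len(FORWARD_PRIMER)
        ancestor = (
            ancestor[:fwd_pos] + FORWARD_PRIMER
            + ancestor[fwd_pos + len(FORWARD_PRIMER):]
        )
        protected = (fwd_pos, fwd_pos + len(FORWARD_PRIMER))
    else:
        ancestor = FORWARD_PRIMER + ancestor[len(FORWARD_PRIMER):]
        protected = (0, len(FORWARD_PRIMER))
    for spec in subtype_spec:
        backbones[spec.phylotype_id] = _mutate(
            rng, ancestor, between_phylotype_rate, protected
        )

    covered = sorted(otu_to_phylotype)
    probs = np.array([model.otus[j].mean_abundance for j in covered])
    probs = probs / probs.sum()
    counts = rng.multinomial(n_clones, probs)

    from Bio.Seq import Seq  # local import keeps module import light

    rev_site = str(Seq(REVERSE_PRIMER).reverse_complement())
    clones: list[CloneSequence] = []
    k = 0
    for j, c in zip(covered, counts):
        phylo = otu_to_phylotype[j]
        target = int(round(model.otus[j].fragment_length))
        for _ in range(c):
            k += 1
            gene = _mutate(rng, backbones[phylo], within_phylotype_rate,
                           protected)
            spacer = ""
            if assay == "ARISA":
                fwd_pos = gene.find(FORWARD_PRIMER)
                # amplicon = gene[fwd_pos:] + spacer; spacer ends in the
                # reverse-primer site so the predicted length hits target
                fixed = (gene_length - fwd_pos) + len(rev_site)
                its_len = target - fixed
                if its_len < 0:
                    raise ValueError(
                        f"OTU fragment length {target} too short for the "
                        "ARISA amplicon overhead"
                    )
                spacer = _random_seq(rng, its_len) + rev_site
                spacer = _scrub_primer_hits(spacer, its_len)
            else:
                cut_site = "ACAGT"  # cut after position 3 of the site
                site_start = target - 3
                if not 0 < site_start <= gene_length - 5:
                    raise ValueError(
                        f"OTU fragment length {target} outside the gene for "
                        "T-RF site planting"
                    )
                gene = _scrub_trf_sites(gene, site_start)
                gene = (gene[:site_start] + cut_site
                        + gene[site_start + 5:])
                gene = _scrub_trf_sites(gene, site_start)
            clones.append(
                CloneSequence(
                    id=f"{library_id}_{k:04d}",
                    library_id=library_id,
                    gene_region=gene,
                    spacer_region=spacer,
                    true_phylotype=phylo,
                    true_otu=j,
                )
            )
    return clones


def _scrub_primer_hits(spacer: str, its_len: int) -> str:
    """Make sure the reverse-primer site occurs only at the spacer's end."""
    from Bio.Seq import Seq

    rev_site = str(Seq(REVERSE_PRIMER).reverse_complement())
    body = spacer[:its_len]
    while rev_site in body:
        i = body.index(rev_site)
        body = body[:i] + ("A" if body[i] != "A" else "C") + body[i + 1:]
    return body + spacer[its_len:]


def write_clones_fasta(clones: Sequence[CloneSequence], path) -> None:
    """FASTA with the planted truth recorded in the description line."""
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    records = []
    for c in clones:
        desc = (
            f"library={c.library_id} gene_length={len(c.gene_region)} "
            f"true_phylotype={c.true_phylotype} true_otu={c.true_otu}"
        )
        records.append(SeqRecord(Seq(c.amplicon), id=c.id, description=desc))
    SeqIO.write(records, str(path), "fasta")


def read_clones_fasta(path) -> list[CloneSequence]:
    """Inverse of :func:`write_clones_fasta`."""
    from Bio import SeqIO

    clones = []
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = dict(
            kv.split("=", 1) for kv in rec.description.split()[1:] if "=" in kv
        )
        glen = int(fields["gene_length"])
        seq = str(rec.seq)
        clones.append(
            CloneSequence(
                id=rec.id,
                library_id=fields.get("library", "LIB"),
                gene_region=seq[:glen],
                spacer_region=seq[glen:],
                true_phylotype=fields.get("true_phylotype") or None,
                true_otu=(
                    int(fields["true_otu"])
                    if fields.get("true_otu", "None") != "None"
                    else None
                ),
            )
        )
    return clones
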