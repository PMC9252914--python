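"""Fully labeled synthetic cohorts for every pipeline stage.

Generates matched INI/REM/REL variant tables under TYPE1/TYPE2 clonal
evolution, CNA segment profiles, germline predisposition variants, a random
reference genome with signature-biased hypermutation bursts, and a stage
reference atlas with mixed bulk accessibility profiles — all with recorded
ground truth and byte-identical reproducibility for a fixed (config, seed).

Generative contract: diploid heterozygous sites, variant af = CCF/2, observed
alt reads ~ Binomial(site depth, af * blast), site depth ~ Poisson(mean
depth).  TYPE1 cases keep the truncal and major clone (and any minor clone)
alive at relapse and add a relapse-private clone; TYPE2 cases zero out the
major clone's private mutations at relapse and expand a minor ancestral
subclone (CCF 0.05-0.25 at diagnosis) to majority, with a larger gain load.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .deconv import DEFAULT_STAGES, ReferenceAtlas
from .errors import ValidationError
from .signatures import CHANNELS, SignatureMatrix, _revcomp
from .variant_io import (
    CNASegment,
    Effect,
    PatientCase,
    Timepoint,
    VariantRecord,
    write_cna_bed,
    write_variant_table,
)

__all__ = [
    "SimulationConfig",
    "CaseTruth",
    "GenomeSampler",
    "simulate_case",
    "simulate_cohort",
    "simulate_atlas_and_mixtures",
    "make_signature_matrix",
    "random_genome",
]

_CODING_EFFECTS = (
    Effect.missense,
    Effect.synonymous,
    Effect.stopgain,
    Effect.frameshift_indel,
    Effect.inframe_indel,
)
_SOMATIC_GENES = (
    "NOTCH1", "FBXW7", "NRAS", "KRAS", "IL7R", "JAK1", "JAK3", "STAT5B",
    "PTEN", "PIK3CA", "NT5C2", "TP53", "KDM6A", "EZH2", "RPL10", "USP7",
)


@dataclass
class SimulationConfig:
    """Knobs for the synthetic cohort; every probability must be in [0, 1]."""

    seed: int = 0
    n_type1: int = 18
    n_type2: int = 20
    clones_per_case: tuple[int, int] = (2, 3)  # subclones in addition to truncal
    mutations_per_clone: tuple[int, int] = (6, 14)
    depth: float = 100.0
    blast_ini: tuple[float, float] = (0.85, 1.0)
    blast_rel: tuple[float, float] = (0.85, 1.0)
    hypermutator_prob: float = 0.15  # applied to TYPE2 cases only
    hypermutator_burst: int = 85  # REL coding gains exceed this strictly
    signature_bias: str = "SIG2"
    n_signatures: int = 3
    cpg_carrier_prob: dict = field(
        default_factory=lambda: {"TYPE1": 0.0, "TYPE2": 0.35}
    )
    cna_segments_per_case: tuple[int, int] = (1, 4)
    cna_loss_prob_type2: float = 0.45
    gains_mean_type1: float = 11.0
    gains_mean_type2: float = 33.0
    n_germline_background: tuple[int, int] = (3, 8)
    genome_length: int = 200_000
    chrom_name: str = "chrS"
    atlas_regions: int = 3000
    atlas_samples_per_type: int = 8
    noise_sigma: float = 0.1
    relapse_days_mean: dict = field(
        default_factory=lambda: {"TYPE1": 500.0, "TYPE2": 900.0}
    )

    def __post_init__(self) -> None:
        for p in (self.hypermutator_prob, self.cna_loss_prob_type2,
                  *self.cpg_carrier_prob.values()):
            if not (0 <= p <= 1):
                raise ValidationError(f"probability out of [0,1]: {p}")


@dataclass
class CaseTruth:
    """Everything needed to recompute the expected pipeline output."""

    patient_id: str
    relapse_type: str
    clone_ccf_ini: dict
    clone_ccf_rel: dict
    variant_clone: dict  # key -> clone name ("" for germline)
    germline_keys: set
    lost_keys: set
    gained_keys: set
    carrier: bool
    hypermutator: bool
    cna_lost: int
    n_gained: int
    blast: dict
    time_to_relapse_days: int
    event_after_relapse: bool


class GenomeSampler:
    """Random reference genome with a trinucleotide-context position index."""

    def __init__(self, sequence: str, chrom: str = "chrS"):
        self.chrom = chrom
        self.sequence = sequence
        self._by_context: dict[str, list[int]] = {}
        for i in range(1, len(sequence) - 1):
            tri = sequence[i - 1 : i + 2]
            if "N" not in tri:
                self._by_context.setdefault(tri, []).append(i)  # 0-based centre

    def as_mapping(self) -> dict[str, str]:
        return {self.chrom: self.sequence}

    def random_position(self, rng: np.random.Generator, used: set[int]) -> int:
        """0-based position with an unambiguous trinucleotide context."""
        for _ in range(10_000):
            i = int(rng.integers(1, len(self.sequence) - 1))
            if i not in used:
                return i
        raise ValidationError("genome exhausted while sampling positions")

    def position_for_channel(
        self, channel: str, rng: np.random.Generator, used: set[int]
    ) -> tuple[int, str, str]:
        """Pick a genome position whose context realises ``channel``.

        Returns (0-based position, ref, alt); the plus-strand context may be
        the reverse complement of the canonical pyrimidine-centred label.
        """
        five, ref, alt, three = channel[0], channel[2], channel[4], channel[6]
        fwd = five + ref + three
        rev = _revcomp(fwd)
        candidates = self._by_context.get(fwd, []) + self._by_context.get(rev, [])
        if not candidates:
            raise ValidationError(f"no genome position with context {channel}")
        for _ in range(10_000):
            i = candidates[int(rng.integers(0, len(candidates)))]
            if i not in used:
                strand_ref = self.sequence[i]
                strand_alt = alt if strand_ref == ref else _revcomp(alt)
                return i, strand_ref, strand_alt
        raise ValidationError(f"context {channel} exhausted")


def random_genome(length: int, rng: np.random.Generator) -> str:
    return "".join(np.asarray(list("ACGT"))[rng.integers(0, 4, size=length)])


def make_signature_matrix(
    rng: np.random.Generator, n_signatures: int = 3
) -> SignatureMatrix:
    """Random, well-separated signature rows (sparse Dirichlet over 96 channels)."""
    probs = rng.dirichlet(np.full(96, 0.15), size=n_signatures)
    probs = np.maximum(probs, 1e-12)
    probs /= probs.sum(axis=1, keepdims=True)
    names = [f"SIG{i + 1}" for i in range(n_signatures)]
    return SignatureMatrix(names=names, probs=probs)


def _sample_reads(
    rng: np.random.Generator, true_af: float, mean_depth: float
) -> tuple[int, int]:
    depth = int(rng.poisson(mean_depth))
    alt = int(rng.binomial(depth, min(true_af, 1.0))) if depth > 0 else 0
    return alt, depth


def _draw_snv(
    rng: np.random.Generator, sampler: GenomeSampler, used: set[int]
) -> tuple[int, str, str]:
    i = sampler.random_position(rng, used)
    ref = sampler.sequence[i]
    alt = rng.choice([b for b in "ACGT" if b != ref])
    return i, ref, str(alt)


def simulate_case(
    type_label: str,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    sampler: GenomeSampler,
    cpg_genes: list[str],
    signatures: SignatureMatrix,
    patient_id: str,
) -> tuple[PatientCase, CaseTruth]:
    """Generate one matched INI/REM/REL case with full ground truth."""
    if type_label not in ("TYPE1", "TYPE2"):
        raise ValidationError(f"unknown relapse type {type_label!r}")
    used: set[int] = set()

    # clone tree: truncal (CCF 1) + major + minor ancestral subclone
    major_ccf_ini = float(rng.uniform(0.65, 0.9))
    minor_ccf_ini = float(rng.uniform(0.05, 0.25))
    if type_label == "TYPE1":
        clone_ccf_ini = {"truncal": 1.0, "major": major_ccf_ini, "minor": minor_ccf_ini}
        clone_ccf_rel = {
            "truncal": 1.0,
            "major": float(rng.uniform(0.7, 1.0)),
            "minor": minor_ccf_ini,  # persists: TYPE1 loses nothing by construction
            "relapse_private": float(rng.uniform(0.6, 0.95)),
        }
        n_gained = int(rng.poisson(cfg.gains_mean_type1))
    else:
        clone_ccf_ini = {"truncal": 1.0, "major": major_ccf_ini, "minor": minor_ccf_ini}
        clone_ccf_rel = {
            "truncal": 1.0,
            "major": 0.0,  # eradicated
            "minor": float(rng.uniform(0.75, 1.0)),  # expands to majority
            "relapse_private": float(rng.uniform(0.6, 0.95)),
        }
        n_gained = int(rng.poisson(cfg.gains_mean_type2))

    hypermutator = type_label == "TYPE2" and bool(rng.random() < cfg.hypermutator_prob)
    carrier = bool(rng.random() < cfg.cpg_carrier_prob.get(type_label, 0.0))

    blast = {
        Timepoint.INI: float(rng.uniform(*cfg.blast_ini)),
        Timepoint.REM: 1.0,
        Timepoint.REL: float(rng.uniform(*cfg.blast_rel)),
    }

    # --- assemble the site table: (key, clone, germline, effect, gene, coding)
    sites: list[dict] = []

    def add_snv(clone: str, germline: bool, effect: Effect, gene: str, coding: bool):
        i, ref, alt = _draw_snv(rng, sampler, used)
        used.add(i)
        sites.append(
            dict(pos=i + 1, ref=ref, alt=alt, clone=clone, germline=germline,
                 effect=effect, gene=gene, coding=coding)
        )

    def random_effect() -> tuple[Effect, str, bool]:
        effect = _CODING_EFFECTS[int(rng.integers(0, len(_CODING_EFFECTS)))]
        gene = _SOMATIC_GENES[int(rng.integers(0, len(_SOMATIC_GENES)))]
        return effect, gene, True

    for clone in ("truncal", "major", "minor"):
        n = int(rng.integers(cfg.mutations_per_clone[0], cfg.mutations_per_clone[1] + 1))
        for _ in range(n):
            effect, gene, coding = random_effect()
            add_snv(clone, False, effect, gene, coding)

    # relapse-private gains; hypermutators get a signature-biased all-coding burst
    if hypermutator:
        n_burst = cfg.hypermutator_burst + 1 + int(rng.poisson(20))
        bias_idx = signatures.names.index(cfg.signature_bias)
        channel_draws = rng.choice(96, size=n_burst, p=signatures.probs[bias_idx])
        for ch in channel_draws:
            i, ref, alt = sampler.position_for_channel(CHANNELS[ch], rng, used)
            used.add(i)
            gene = _SOMATIC_GENES[int(rng.integers(0, len(_SOMATIC_GENES)))]
            sites.append(
                dict(pos=i + 1, ref=ref, alt=alt, clone="relapse_private",
                     germline=False, effect=Effect.missense, gene=gene, coding=True)
            )
    else:
        for _ in range(n_gained):
            effect, gene, coding = random_effect()
            add_snv("relapse_private", False, effect, gene, coding)

    # germline background + planted predisposition loss-of-function variants
    n_bg = int(rng.integers(cfg.n_germline_background[0], cfg.n_germline_background[1] + 1))
    for _ in range(n_bg):
        add_snv("", True, Effect.synonymous, "", True)
    if carrier:
        for _ in range(int(rng.integers(1, 3))):
            gene = cpg_genes[int(rng.integers(0, len(cpg_genes)))]
            lof = (Effect.stopgain, Effect.frameshift_indel, Effect.splice_donor)
            add_snv("", True, lof[int(rng.integers(0, 3))], gene, True)

    # --- sample reads at every site for all three timepoints
    variants: dict[Timepoint, list[VariantRecord]] = {tp: [] for tp in Timepoint}
    for s in sites:
        for tp in Timepoint:
            if s["germline"]:
                true_af = 0.5
            elif tp is Timepoint.REM:
                true_af = 0.0
            else:
                ccf = (clone_ccf_ini if tp is Timepoint.INI else clone_ccf_rel).get(
                    s["clone"], 0.0
                )
                true_af = ccf * blast[tp] / 2.0
            alt_count, depth = _sample_reads(rng, true_af, cfg.depth)
            variants[tp].append(
                VariantRecord(
                    chrom=sampler.chrom,
                    pos=s["pos"],
                    ref=s["ref"],
                    alt=s["alt"],
                    alt_count=alt_count,
                    depth=depth,
                    effect=s["effect"],
                    gene=s["gene"],
                    coding=s["coding"],
                    timepoint=tp,
                )
            )

    # --- CNA profiles
    n_seg = int(rng.integers(cfg.cna_segments_per_case[0], cfg.cna_segments_per_case[1] + 1))
    ini_segs: list[CNASegment] = []
    starts = sorted(rng.choice(50_000, size=n_seg, replace=False).tolist())
    for k, st in enumerate(starts):
        start = int(st) * 2500  # spacing exceeds max length: segments stay disjoint
        length = int(rng.integers(500, 2000))
        state = ("gain", "loss", "cnloh")[int(rng.integers(0, 3))]
        ini_segs.append(
            CNASegment(chrom=sampler.chrom, start=start, end=start + length, state=state)
        )
    cna_lost = 0
    if type_label == "TYPE2" and ini_segs and rng.random() < cfg.cna_loss_prob_type2:
        cna_lost = int(rng.integers(1, len(ini_segs) + 1))
    rel_segs = list(ini_segs[cna_lost:])

    days = max(30, int(rng.normal(cfg.relapse_days_mean[type_label], 150.0)))
    event = bool(rng.random() < 0.5)

    case = PatientCase(
        patient_id=patient_id,
        variants=variants,
        blast_fraction=dict(blast),
        cna_profiles={Timepoint.INI: ini_segs, Timepoint.REL: rel_segs},
        time_to_relapse_days=days,
        event_after_relapse=event,
    )
    key_of = lambda s: (sampler.chrom, s["pos"], s["ref"], s["alt"])
    lost_keys = {
        key_of(s)
        for s in sites
        if not s["germline"]
        and clone_ccf_ini.get(s["clone"], 0.0) > 0
        and clone_ccf_rel.get(s["clone"], 0.0) == 0.0
    }
    gained_keys = {
        key_of(s)
        for s in sites
        if not s["germline"]
        and clone_ccf_ini.get(s["clone"], 0.0) == 0.0
        and clone_ccf_rel.get(s["clone"], 0.0) > 0
    }
    truth = CaseTruth(
        patient_id=patient_id,
        relapse_type=type_label,
        clone_ccf_ini=clone_ccf_ini,
        clone_ccf_rel=clone_ccf_rel,
        variant_clone={key_of(s): s["clone"] for s in sites},
        germline_keys={key_of(s) for s in sites if s["germline"]},
        lost_keys=lost_keys,
        gained_keys=gained_keys,
        carrier=carrier,
        hypermutator=hypermutator,
        cna_lost=cna_lost,
        n_gained=len(gained_keys),
        blast={tp.value: b for tp, b in blast.items()},
        time_to_relapse_days=days,
        event_after_relapse=event,
    )
    return case, truth


def simulate_atlas_and_mixtures(
    cfg: SimulationConfig, rng: np.random.Generator
) -> tuple[ReferenceAtlas, "np.ndarray", list[str], "np.ndarray", list[str]]:
    """Stage atlas with planted stage-specific regions, plus mixed bulk profiles.

    Returns (atlas, profiles[n_samples, n_regions], sample names,
    true_mixtures[n_samples, 5], sample type labels).  TYPE1-style samples
    have a dominant component >= 0.8; TYPE2-style <= 0.5.  Profiles are
    convex mixtures of the CPM-scaled stage columns times log-normal noise
    (sigma = cfg.noise_sigma).
    """
    n_stages = len(DEFAULT_STAGES)
    R = cfg.atlas_regions
    if R < 10 * n_stages:
        raise ValidationError("atlas_regions must be >= 10x the stage count")
    values = rng.lognormal(mean=1.0, sigma=0.5, size=(R, n_stages))
    block = R // (2 * n_stages)  # planted stage-specific high-accessibility regions
    for s in range(n_stages):
        idx = slice(s * block, (s + 1) * block)
        values[idx, s] += rng.uniform(40.0, 120.0, size=block)
    atlas = ReferenceAtlas(
        region_ids=[f"region_{i:05d}" for i in range(R)],
        stages=list(DEFAULT_STAGES),
        values=values,
    )

    from .deconv import cpm_scale

    cpm = cpm_scale(values)
    mixtures: list[np.ndarray] = []
    labels: list[str] = []
    names: list[str] = []
    for t, tname in (("TYPE1", "t1"), ("TYPE2", "t2")):
        for k in range(cfg.atlas_samples_per_type):
            if t == "TYPE1":
                dom = int(rng.integers(0, n_stages))
                w = rng.dirichlet(np.ones(n_stages)) * 0.2
                w[dom] = 0.0
                w = w / w.sum() * (1.0 - float(rng.uniform(0.8, 0.95)))
                w[dom] = 1.0 - w.sum()
            else:
                w = rng.dirichlet(np.ones(n_stages) * 4.0)
                while w.max() > 0.5:
                    w = rng.dirichlet(np.ones(n_stages) * 4.0)
            mixtures.append(w)
            labels.append(t)
            names.append(f"{tname}_s{k}")
    W = np.vstack(mixtures)
    clean = W @ cpm.T  # n_samples x R
    if cfg.noise_sigma > 0:
        noise = rng.lognormal(mean=0.0, sigma=cfg.noise_sigma, size=clean.shape)
        profiles = clean * noise
    else:
        profiles = clean
    return atlas, profiles, names, W, labels


def simulate_cohort(
    cfg: SimulationConfig, outdir: str | Path | None = None
) -> dict:
    """Generate the full fixture set; optionally write it to ``outdir``.

    Returns a dict with cases, truths, genome sampler, signature matrix, CPG
    gene list, atlas, profiles and mixture truth.  When writing, pre-existing
    target files raise ValidationError (no silent overwrites).
    """
    rng = np.random.default_rng(cfg.seed)
    genome = random_genome(cfg.genome_length, rng)
    sampler = GenomeSampler(genome, cfg.chrom_name)
    signatures = make_signature_matrix(rng, cfg.n_signatures)
    cpg_genes = [f"CPG{i:03d}" for i in range(1, 61)]

    cases: list[PatientCase] = []
    truths: list[CaseTruth] = []
    labels = ["TYPE1"] * cfg.n_type1 + ["TYPE2"] * cfg.n_type2
    for i, label in enumerate(labels, start=1):
        case, truth = simulate_case(
            label, cfg, rng, sampler, cpg_genes, signatures, patient_id=f"P{i:02d}"
        )
        cases.append(case)
        truths.append(truth)

    atlas, profiles, sample_names, true_mix, mix_labels = simulate_atlas_and_mixtures(
        cfg, rng
    )
    out = {
        "cases": cases,
        "truths": truths,
        "sampler": sampler,
        "signatures": signatures,
        "cpg_genes": cpg_genes,
        "atlas": atlas,
        "profiles": profiles,
        "profile_names": sample_names,
        "true_mixtures": true_mix,
        "mixture_labels": mix_labels,
    }
    if outdir is not None:
        _write_fixtures(out, cfg, Path(outdir))
    return out


def _require_new(path: Path) -> Path:
    if path.exists():
        raise ValidationError(f"refusing to overwrite existing fixture: {path}")
    return path


def _write_fixtures(sim: dict, cfg: SimulationConfig, outdir: Path) -> None:
    import pandas as pd

    outdir.mkdir(parents=True, exist_ok=True)
    sampler: GenomeSampler = sim["sampler"]
    with open(_require_new(outdir / "genome.fa"), "w") as fh:
        fh.write(f">{sampler.chrom}\n")
        seq = sampler.sequence
        for i in range(0, len(seq), 80):
            fh.write(seq[i : i + 80] + "\n")
    sim["signatures"].to_tsv(_require_new(outdir / "signatures.tsv"))
    with open(_require_new(outdir / "cpg_genes.txt"), "w") as fh:
        fh.write("# synthetic predisposition gene list\n")
        for g in sim["cpg_genes"]:
            fh.write(g + "\n")

    cases_dir = outdir / "cases"
    meta_rows = []
    for case, truth in zip(sim["cases"], sim["truths"]):
        cdir = cases_dir / case.patient_id
        cdir.mkdir(parents=True, exist_ok=True)
        all_records = [r for tp in Timepoint for r in case.timepoint(tp)]
        write_variant_table(
            all_records, _require_new(cdir / "variants.tsv"), patient_id=case.patient_id
        )
        for tp in (Timepoint.INI, Timepoint.REL):
            write_cna_bed(
                case.cna_profiles.get(tp, []),
                _require_new(cdir / f"cna_{tp.value}.bed"),
            )
        with open(_require_new(cdir / "meta.tsv"), "w") as fh:
            fh.write("field\tvalue\n")
            for tp in Timepoint:
                fh.write(f"blast_{tp.value}\t{case.blast_fraction[tp]!r}\n")
            fh.write(f"time_to_relapse_days\t{case.time_to_relapse_days}\n")
            fh.write(f"event_after_relapse\t{int(case.event_after_relapse)}\n")
        meta_rows.append(
            dict(
                patient_id=truth.patient_id,
                relapse_type=truth.relapse_type,
                carrier=int(truth.carrier),
                hypermutator=int(truth.hypermutator),
                n_lost=len(truth.lost_keys),
                n_gained=truth.n_gained,
                cna_lost=truth.cna_lost,
                time_to_relapse_days=truth.time_to_relapse_days,
                event_after_relapse=int(truth.event_after_relapse),
            )
        )
    pd.DataFrame(meta_rows).to_csv(
        _require_new(outdir / "truth.tsv"), sep="\t", index=False
    )

    sim["atlas"].to_tsv(_require_new(outdir / "atlas.tsv"))
    prof = pd.DataFrame(
        sim["profiles"].T, index=sim["atlas"].region_ids, columns=sim["profile_names"]
    )
    prof.index.name = "region_id"
    prof.to_csv(_require_new(outdir / "profiles.tsv"), sep="\t")
    mix = pd.DataFrame(
        sim["true_mixtures"], index=sim["profile_names"], columns=sim["atlas"].stages
    )
    mix.insert(0, "type", sim["mixture_labels"])
    mix.index.name = "sample"
    mix.to_csv(_require_new(outdir / "mixture_truth.tsv"), sep="\t")
    # group membership is an input to the cohort comparison, not ground truth
    with open(_require_new(outdir / "profile_labels.tsv"), "w") as fh:
        fh.write("sample\ttype\n")
        for name, label in zip(sim["profile_names"], sim["mixture_labels"]):
            fh.write(f"{name}\t{label}\n")
    with open(_require_new(outdir / "config_used.txt"), "w") as fh:
        fh.write(repr(dataclasses.asdict(cfg)) + "\n")
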