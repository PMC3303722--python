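"""Paired two-library small-RNA simulator with full ground truth.

Generates random pre-miRNA hairpins with a mature miRNA planted on each
arm, then draws collapsed read libraries for two conditions: per-hairpin
5p/3p arm ratios set the arm split, reads vary around the planted span
according to a configurable isomiR offset distribution, and a configurable
fraction of reads carries a non-templated 3' addition fragment.  Every
emitted read's origin (hairpin, span, appended fragment) is recorded, so
each pipeline stage can be checked against known truth.

Identifiability construction
----------------------------
A 3' addition is only recoverable by trim-rescue mapping if its first base
differs from the next templated hairpin base.  Rather than mutate drawn
fragments (which would distort the fragment distribution being planted),
the generator fixes a spacer base C throughout each mature's 3' junction
zone — the last five mature nucleotides and the six positions past the
mature end, covering every junction an end offset in [-5, +5] can create —
and requires that no addition fragment start with C.  Published addition
fragments are A/U-dominated and none of the common ones start with C, so
the constraint is biologically mild; it does mean this simulator cannot
emulate real additions that coincidentally extend the template (those are
invisible to any exact-match pipeline and are documented as such).

Hairpins are resampled until no 18-mer occurs twice anywhere in the
reference, guaranteeing unambiguous mapping for oracle tests.
"""
from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .mirbase import MatureAnnotation, PreMiRNA, arm_of_span, write_annotation_tsv, write_hairpin_fasta
from .preprocess import Library, UniqueRead, write_collapsed_tsv

SPACER_BASE = "C"
_BASES = np.array(list("ACGU"))

#: default isomiR offset distribution: reference form dominant, 3'-end
#: variation more common than 5'-end variation (the seed end is constrained)
DEFAULT_OFFSET_PROBS: dict[tuple[int, int], float] = {
    (0, 0): 0.35,
    (0, -1): 0.13,
    (0, 1): 0.11,
    (0, -2): 0.08,
    (0, 2): 0.06,
    (-1, 0): 0.07,
    (1, 0): 0.07,
    (0, -3): 0.04,
    (0, 3): 0.03,
    (-1, -1): 0.03,
    (1, 1): 0.02,
    (-2, 0): 0.01,
}

#: fragment shares among addition events, normal-gastric-library profile;
#: the eight named fragments follow the published table, three fillers
#: (UUU, GA, UG) absorb the unlisted 6.52% remainder.
ADDITION_FRACTIONS: dict[str, float] = {
    "A": 0.5093,
    "U": 0.3072,
    "AA": 0.0339,
    "UA": 0.0228,
    "UU": 0.0216,
    "AU": 0.0153,
    "G": 0.0140,
    "AAA": 0.0107,
    "UUU": 0.02,
    "GA": 0.02,
    "UG": 0.0252,
}

DEFAULT_ADDITION_RATE = 0.14  # fraction of reads carrying an addition


def default_addition_probs(rate: float = DEFAULT_ADDITION_RATE) -> dict[str, float]:
    """Fragment distribution including the empty (no-addition) fragment."""
    probs = {"": 1.0 - rate}
    probs.update({frag: rate * f for frag, f in ADDITION_FRACTIONS.items()})
    return probs


class InfeasibleConfigError(ValueError):
    """Raised when a simulation configuration cannot produce valid hairpins."""


@dataclass
class SimulationConfig:
    """Study conditions for one paired-library simulation.

    arm_ratio_a/b are expected 5p/3p count ratios (scalar, applied to every
    hairpin, or one value per hairpin).  library_depths are total read
    counts per library, split evenly across hairpins.  A fraction of
    hairpins is annotated on only one arm in the public annotation file
    (both arms always exist in the truth), exercising opposite-arm
    detection.
    """

    n_hairpins: int = 20
    hairpin_length_range: tuple[int, int] = (70, 90)
    mature_length_range: tuple[int, int] = (21, 22)
    arm_ratio_a: float | Sequence[float] = 2.0
    arm_ratio_b: float | Sequence[float] = 2.0
    isomir_offset_probs: dict[tuple[int, int], float] = field(
        default_factory=lambda: dict(DEFAULT_OFFSET_PROBS)
    )
    #: optional library-B offset distribution (defaults to the library-A one);
    #: lets tests plant isomiR-pattern shifts between conditions
    isomir_offset_probs_b: dict[tuple[int, int], float] | None = None
    addition_probs: dict[str, float] = field(default_factory=default_addition_probs)
    library_depths: tuple[int, int] = (100_000, 100_000)
    unannotated_arm_fraction: float = 0.25
    library_names: tuple[str, str] = ("simN", "simT")
    max_start_offset: int = 2
    max_end_offset: int = 5
    read_length_range: tuple[int, int] = (18, 25)
    seed: int = 0

    def ratios(self, which: str) -> list[float]:
        r = self.arm_ratio_a if which == "a" else self.arm_ratio_b
        if np.isscalar(r):
            return [float(r)] * self.n_hairpins
        r = list(r)
        if len(r) != self.n_hairpins:
            raise InfeasibleConfigError(
                f"arm_ratio_{which}: need {self.n_hairpins} values, got {len(r)}"
            )
        return [float(v) for v in r]

    def offset_probs(self, which: str) -> dict[tuple[int, int], float]:
        if which == "b" and self.isomir_offset_probs_b is not None:
            return self.isomir_offset_probs_b
        return self.isomir_offset_probs

    def validate(self) -> None:
        if self.n_hairpins < 1:
            raise InfeasibleConfigError("n_hairpins must be >= 1")
        lo, hi = self.hairpin_length_range
        m_lo, m_hi = self.mature_length_range
        # layout: 5p start <= max_start_offset+3, >=8 nt loop, 6 nt 3' tail
        if lo < 2 * m_hi + self.max_start_offset + 16:
            raise InfeasibleConfigError(
                f"hairpin length {lo} too short for two {m_hi} nt matures "
                f"(need >= {2 * m_hi + self.max_start_offset + 16})"
            )
        for which in ("a", "b"):
            probs = self.offset_probs(which)
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise InfeasibleConfigError(f"isomiR offset probabilities sum to {total}")
            for so, eo in probs:
                if abs(so) > self.max_start_offset or abs(eo) > self.max_end_offset:
                    raise InfeasibleConfigError(
                        f"offset ({so},{eo}) outside the mapper acceptance windows"
                    )
                for m in (m_lo, m_hi):
                    length = m + eo - so
                    if not (self.read_length_range[0] <= length <= self.read_length_range[1]):
                        raise InfeasibleConfigError(
                            f"offset ({so},{eo}) with {m} nt mature gives a "
                            f"{length} nt read outside {self.read_length_range}"
                        )
            for r in self.ratios(which):
                if r <= 0:
                    raise InfeasibleConfigError("arm ratios must be positive")
        total = sum(self.addition_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise InfeasibleConfigError(f"addition probabilities sum to {total}")
        for frag in self.addition_probs:
            if frag == "":
                continue
            if set(frag) - set("ACGU"):
                raise InfeasibleConfigError(f"addition fragment {frag!r} not RNA")
            if frag[0] == SPACER_BASE:
                raise InfeasibleConfigError(
                    f"addition fragment {frag!r} starts with the spacer base "
                    f"{SPACER_BASE!r} and would be invisible to trim-rescue mapping"
                )
            if len(frag) > self.max_end_offset:
                raise InfeasibleConfigError(f"addition fragment {frag!r} longer than trim window")
        if not (0.0 <= self.unannotated_arm_fraction <= 1.0):
            raise InfeasibleConfigError("unannotated_arm_fraction must be in [0, 1]")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["isomir_offset_probs"] = {f"{k[0]},{k[1]}": v for k, v in self.isomir_offset_probs.items()}
        if self.isomir_offset_probs_b is not None:
            d["isomir_offset_probs_b"] = {
                f"{k[0]},{k[1]}": v for k, v in self.isomir_offset_probs_b.items()
            }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for key in ("isomir_offset_probs", "isomir_offset_probs_b"):
            if d.get(key):
                d[key] = {
                    tuple(int(x) for x in k.split(",")): float(v) for k, v in d[key].items()
                }
        for key in ("hairpin_length_range", "mature_length_range", "library_depths",
                    "library_names", "read_length_range"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass(frozen=True)
class ReadOrigin:
    """Where one simulated read sequence came from."""

    premirna_id: str
    arm: str
    map_start: int
    map_end: int
    start_offset: int
    end_offset: int
    fragment: str


@dataclass
class GroundTruth:
    """Realized per-read truth for one simulation."""

    origins: dict[str, ReadOrigin]  # read sequence -> origin
    counts: dict[str, dict[str, float]]  # lib label -> {sequence: count}
    arm_counts: dict[str, dict[tuple[str, str], float]]  # lib -> {(hairpin, arm): count}
    offset_counts: dict[str, dict[tuple[str, str], Counter]]  # lib -> {(hp, arm): {(so,eo): n}}
    fragment_counts: dict[str, Counter]  # lib -> {fragment: count} (nonempty only)
    template_counts: dict[str, dict[tuple[str, str], Counter]]  # lib -> {(hp,arm): {template seq: n}}

    def arm_ratio(self, lib: str, premirna_id: str) -> float:
        c5 = self.arm_counts[lib].get((premirna_id, "5p"), 0.0)
        c3 = self.arm_counts[lib].get((premirna_id, "3p"), 0.0)
        return c5 / c3 if c3 else float("inf")


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    hairpins: dict[str, PreMiRNA]
    annotations_full: list[MatureAnnotation]
    annotations_public: list[MatureAnnotation]
    libraries: tuple[Library, Library]
    ground_truth: GroundTruth

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write the dataset in exactly the formats the pipeline consumes."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "hairpins": outdir / "hairpins.fa",
            "annotations": outdir / "annotations.tsv",
            "annotations_full": outdir / "annotations_full.tsv",
            "reads_a": outdir / f"reads_{self.config.library_names[0]}.tsv",
            "reads_b": outdir / f"reads_{self.config.library_names[1]}.tsv",
            "config": outdir / "config.yaml",
            "origins": outdir / "origins.tsv",
        }
        write_hairpin_fasta(self.hairpins, paths["hairpins"])
        write_annotation_tsv(self.annotations_public, paths["annotations"])
        write_annotation_tsv(self.annotations_full, paths["annotations_full"])
        write_collapsed_tsv(self.libraries[0], paths["reads_a"])
        write_collapsed_tsv(self.libraries[1], paths["reads_b"])
        self.config.to_yaml(paths["config"])
        la, lb = self.config.library_names
        with open(paths["origins"], "w") as fh:
            fh.write(
                "sequence\tpremirna_id\tarm\tmap_start\tmap_end\tstart_offset\t"
                f"end_offset\tfragment\tcount_{la}\tcount_{lb}\n"
            )
            for seq in sorted(self.ground_truth.origins):
                o = self.ground_truth.origins[seq]
                ca = self.ground_truth.counts[la].get(seq, 0)
                cb = self.ground_truth.counts[lb].get(seq, 0)
                fh.write(
                    f"{seq}\t{o.premirna_id}\t{o.arm}\t{o.map_start}\t{o.map_end}\t"
                    f"{o.start_offset}\t{o.end_offset}\t{o.fragment}\t{ca:g}\t{cb:g}\n"
                )
        return paths


def _sample_hairpin(
    rng: np.random.Generator, config: SimulationConfig, kmer_index: set[str], name: str
) -> tuple[PreMiRNA, MatureAnnotation, MatureAnnotation]:
    """Sample one hairpin with planted matures, unique at the 18-mer level."""
    lo, hi = config.hairpin_length_range
    m_lo, m_hi = config.mature_length_range
    for _ in range(1000):
        length = int(rng.integers(lo, hi + 1))
        m5 = int(rng.integers(m_lo, m_hi + 1))
        m3 = int(rng.integers(m_lo, m_hi + 1))
        s5 = int(rng.integers(config.max_start_offset + 1, config.max_start_offset + 4))
        e5 = s5 + m5 - 1
        e3 = length - 6
        s3 = e3 - m3 + 1
        if s3 - e5 - 1 < 8:
            continue
        seq = rng.choice(_BASES, size=length)
        # spacer zones guaranteeing appended fragments mismatch the template
        for end in (e5, e3):
            zone_lo = max(0, end - 5)  # 0-based: last 5 mature nt ...
            zone_hi = min(length, end + 6)  # ... through 6 nt past the mature
            seq[zone_lo:zone_hi] = SPACER_BASE
        s = "".join(seq)
        kmers = {s[i : i + 18] for i in range(length - 17)}
        if len(kmers) != length - 17 or kmers & kmer_index:
            continue
        assert arm_of_span(s5, e5, length) == "5p" and arm_of_span(s3, e3, length) == "3p"
        kmer_index |= kmers
        hp = PreMiRNA(name, s)
        ann5 = MatureAnnotation(f"{name}-5p", name, s5, e5, "5p")
        ann3 = MatureAnnotation(f"{name}-3p", name, s3, e3, "3p")
        return hp, ann5, ann3
    raise InfeasibleConfigError(
        "could not sample an 18-mer-unique hairpin; relax the length ranges"
    )


def simulate(config: SimulationConfig) -> SimulatedDataset:
    """Run one simulation; identical config (incl. seed) gives identical output."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    kmer_index: set[str] = set()
    hairpins: dict[str, PreMiRNA] = {}
    ann_by_hp: dict[str, tuple[MatureAnnotation, MatureAnnotation]] = {}
    for i in range(config.n_hairpins):
        name = f"syn-mir-{i + 1:03d}"
        hp, ann5, ann3 = _sample_hairpin(rng, config, kmer_index, name)
        hairpins[name] = hp
        ann_by_hp[name] = (ann5, ann3)
    annotations_full = [a for pair in ann_by_hp.values() for a in pair]

    # hide one arm on a fraction of hairpins in the public annotation file
    n_hidden = int(round(config.unannotated_arm_fraction * config.n_hairpins))
    hidden_ids = list(rng.choice(config.n_hairpins, size=n_hidden, replace=False)) if n_hidden else []
    hidden_arm: dict[str, str] = {}
    for idx in hidden_ids:
        hid = f"syn-mir-{int(idx) + 1:03d}"
        hidden_arm[hid] = "5p" if rng.random() < 0.5 else "3p"
    annotations_public = [
        a for a in annotations_full if hidden_arm.get(a.premirna_id) != a.arm
    ]

    fragments = sorted(config.addition_probs)
    frag_probs = np.array([config.addition_probs[f] for f in fragments])

    origins: dict[str, ReadOrigin] = {}
    counts: dict[str, dict[str, float]] = {}
    arm_counts: dict[str, dict[tuple[str, str], float]] = {}
    offset_counts: dict[str, dict[tuple[str, str], Counter]] = {}
    fragment_counts: dict[str, Counter] = {}
    template_counts: dict[str, dict[tuple[str, str], Counter]] = {}
    libraries = []

    for lib_idx, lib_name in enumerate(config.library_names):
        which = "a" if lib_idx == 0 else "b"
        depth = config.library_depths[lib_idx]
        ratios = config.ratios(which)
        offsets = sorted(config.offset_probs(which))
        offset_p = np.array([config.offset_probs(which)[o] for o in offsets])
        lib_counts: dict[str, float] = defaultdict(float)
        lib_arms: dict[tuple[str, str], float] = defaultdict(float)
        lib_offsets: dict[tuple[str, str], Counter] = defaultdict(Counter)
        lib_frags: Counter = Counter()
        lib_templates: dict[tuple[str, str], Counter] = defaultdict(Counter)

        per_hairpin = depth // config.n_hairpins
        for h_idx, (hid, hp) in enumerate(hairpins.items()):
            if per_hairpin == 0:
                continue
            p5 = ratios[h_idx] / (1.0 + ratios[h_idx])
            arm_p = np.array([p5, 1.0 - p5])
            # joint combo distribution: arm x offset x fragment
            probs = (
                arm_p[:, None, None] * offset_p[None, :, None] * frag_probs[None, None, :]
            ).ravel()
            draw = rng.multinomial(per_hairpin, probs).reshape(2, len(offsets), len(fragments))
            for a_idx, ann in enumerate(ann_by_hp[hid]):
                for o_idx, (so, eo) in enumerate(offsets):
                    rs, re_ = ann.start + so, ann.end + eo
                    template = hp.subseq(rs, re_)
                    for f_idx, frag in enumerate(fragments):
                        n = int(draw[a_idx, o_idx, f_idx])
                        if n == 0:
                            continue
                        seq = template + frag
                        lib_counts[seq] += n
                        lib_arms[(hid, ann.arm)] += n
                        lib_offsets[(hid, ann.arm)][(so, eo)] += n
                        lib_templates[(hid, ann.arm)][template] += n
                        if frag:
                            lib_frags[frag] += n
                        if seq not in origins:
                            origins[seq] = ReadOrigin(hid, ann.arm, rs, re_, so, eo, frag)

        reads = [
            UniqueRead(seq, cnt)
            for seq, cnt in sorted(lib_counts.items(), key=lambda kv: (-kv[1], kv[0]))
        ]
        total = int(sum(lib_counts.values()))
        libraries.append(
            Library(name=lib_name, reads=reads, total_raw=total, total_clean=total, total_used=total)
        )
        counts[lib_name] = dict(lib_counts)
        arm_counts[lib_name] = dict(lib_arms)
        offset_counts[lib_name] = dict(lib_offsets)
        fragment_counts[lib_name] = lib_frags
        template_counts[lib_name] = dict(lib_templates)

    truth = GroundTruth(
        origins=origins,
        counts=counts,
        arm_counts=arm_counts,
        offset_counts=offset_counts,
        fragment_counts=fragment_counts,
        template_counts=template_counts,
    )
    return SimulatedDataset(
        config=config,
        hairpins=hairpins,
        annotations_full=annotations_full,
        annotations_public=annotations_public,
        libraries=(libraries[0], libraries[1]),
        ground_truth=truth,
    )


def recovery_report(
    truth: GroundTruth,
    result,  # PipelineResult from isomirarm.pipeline
    *,
    ratio_rel_tol: float = 0.2,
    tv_tol: float = 0.05,
    addition_tol_points: float = 0.6,
    origin_min_fraction: float = 0.99,
) -> dict:
    """Compare pipeline outputs on simulated data against the realized truth.

    Reports, per hairpin and library: estimated vs true arm ratios (relative
    error), total-variation distance between true and recovered isomiR
    template distributions, per-fragment addition-percentage errors, and the
    read-count-weighted fraction of mapped reads placed at their true locus.
    Pass flags apply the configured tolerances.
    """
    la, lb = result.labels
    report: dict = {"arm_ratios": {}, "isomir_tv": {}, "additions": {}, "origins": {}}

    # arm ratios -----------------------------------------------------------
    est = result.arm_counts.set_index("premirna_id")
    ratio_ok = True
    col = {la: ("N5p", "N3p"), lb: ("T5p", "T3p")}
    for lib in (la, lb):
        for hid in est.index:
            true_r = truth.arm_ratio(lib, hid)
            c5, c3 = est.loc[hid, col[lib][0]], est.loc[hid, col[lib][1]]
            est_r = c5 / c3 if c3 else float("inf")
            if true_r == float("inf") or true_r == 0:
                rel_err = 0.0 if est_r == true_r else float("inf")
            else:
                rel_err = abs(est_r - true_r) / true_r
            ok = rel_err <= ratio_rel_tol
            ratio_ok &= ok
            report["arm_ratios"][(lib, hid)] = {
                "true": true_r, "estimated": est_r, "rel_error": rel_err, "pass": ok,
            }

    # isomiR distributions (by mapped template sequence) -------------------
    template_est: dict[str, dict[tuple[str, str], Counter]] = {}
    ann_arm = {a.mature_id: (a.premirna_id, a.arm) for a in result.annotations}
    for lib in (la, lb):
        acc: dict[tuple[str, str], Counter] = defaultdict(Counter)
        for iso in result.libs[lib].isomirs:
            key = ann_arm[iso.mature_id]
            acc[key][iso.sequence] += iso.count
        template_est[lib] = acc
    tv_ok = True
    for lib in (la, lb):
        for key, true_counter in truth.template_counts[lib].items():
            n_true = sum(true_counter.values())
            est_counter = template_est[lib].get(key, Counter())
            n_est = sum(est_counter.values())
            seqs = set(true_counter) | set(est_counter)
            tv = 0.5 * sum(
                abs(
                    true_counter.get(s, 0) / n_true
                    - (est_counter.get(s, 0) / n_est if n_est else 0.0)
                )
                for s in seqs
            )
            ok = tv <= tv_tol
            tv_ok &= ok
            report["isomir_tv"][(lib, key)] = {"tv": tv, "pass": ok}

    # addition fragments ---------------------------------------------------
    add_ok = True
    for lib in (la, lb):
        true_frags = truth.fragment_counts[lib]
        total_true = sum(true_frags.values())
        table = result.libs[lib].additions.table.set_index("fragment")
        for frag, cnt in true_frags.items():
            true_pct = 100.0 * cnt / total_true if total_true else 0.0
            est_pct = float(table["pct"].get(frag, 0.0))
            err = abs(est_pct - true_pct)
            ok = err <= addition_tol_points
            add_ok &= ok
            report["additions"][(lib, frag)] = {
                "true_pct": true_pct, "estimated_pct": est_pct, "error": err, "pass": ok,
            }

    # per-read origin recovery --------------------------------------------
    origin_ok = True
    for lib in (la, lb):
        correct = 0.0
        total = 0.0
        for mr in result.libs[lib].mapped:
            total += mr.count
            origin = truth.origins.get(mr.read.sequence)
            if origin is None:
                raise ValueError(f"mapped read {mr.read.sequence!r} has no recorded origin")
            if (
                origin.premirna_id == mr.premirna_id
                and origin.map_start == mr.map_start
                and origin.map_end == mr.map_end
            ):
                correct += mr.count
        frac = correct / total if total else 1.0
        ok = frac >= origin_min_fraction
        origin_ok &= ok
        report["origins"][lib] = {"fraction_correct": frac, "pass": ok}

    report["pass"] = {
        "arm_ratios": bool(ratio_ok),
        "isomir_tv": bool(tv_ok),
        "additions": bool(add_ok),
        "origins": bool(origin_ok),
        "all": bool(ratio_ok and tv_ok and add_ok and origin_ok),
    }
    return report
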