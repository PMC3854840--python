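"""Synthetic mtDNA cohort generator with known truth.

Emulates mtDNA-enriched paired-end brain libraries: a population of
full-length circular molecules, each carrying at most one rearrangement
(common deletion, major-arc deletion between direct repeats, control-region
multimer (CRM), control-region deletion (CRD)) plus per-molecule point
mutations with a transition-dominated, strand-biased spectrum, a
control-region excess, and an m.3243 hotspot.  Fragments are sampled from
molecules (not from the reference) so that junction-spanning read counts
scale with molecule frequency exactly as the per-mtDNA estimator assumes;
library chimeras and 8-oxoG-like G>T/C>A errors are injected at the
fragment level, and 2x100 bp mates with configurable Phred profiles are
emitted.

Deletion-class frequencies are molecule fractions (one junction per
molecule).  CRM frequency is the tandem-duplication junction burden per
genome equivalent: a CRM molecule is a circular tandem array of one short
control-region unit, so a single molecule carries one junction per unit
copy; frequencies are realized by drawing enough CRM molecules to reach the
requested junction burden.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reference import CircularGenome, revcomp_codes, wrap_pos

logger = logging.getLogger(__name__)

CLASSES = ("reference", "common_deletion", "major_arc", "crm", "crd")

#: base changes on the reference (L-)strand, lexicographic order
BASE_CHANGES = (
    "A>C", "A>G", "A>T", "C>A", "C>G", "C>T",
    "G>A", "G>C", "G>T", "T>A", "T>C", "T>G",
)

#: default change weights: ~90% transitions with the L-strand bias
#: (G>A over C>T, T>C over A>G) attributed to heavy-strand cytosine
#: deamination.
DEFAULT_CHANGE_WEIGHTS = {
    "G>A": 0.40, "T>C": 0.22, "C>T": 0.18, "A>G": 0.10,
    "A>C": 0.0125, "A>T": 0.0125, "C>A": 0.0125, "C>G": 0.0125,
    "G>C": 0.0125, "G>T": 0.0125, "T>A": 0.0125, "T>G": 0.0125,
}

# canonical junctions, non-overlapping convention (1-based CRS):
# molecule reads ...b5 then resumes at b3.
COMMON_DELETION_JUNCTION = (8482, 13460)  # m.8483_13459del4977
CRD_PROTOTYPE_JUNCTION = (306, 357)  # m.307_356del50
MAJOR_ARC_WINDOW = (5576, 15976)
CRM_WINDOW = (16492, 59)  # wraps the CRS origin


@dataclass
class SampleTruth:
    """Generating parameters for one simulated specimen.

    Rearrangement frequencies are per mtDNA equivalent; ``snv_rate_per_bp``
    is the expected somatic point-mutation burden per base pair (each
    molecule draws Poisson(rate x genome length) mutations, so the expected
    per-position variant fraction equals the rate).  ``hotspot_3243_freq``
    is the fraction of molecules carrying m.3243A>G.  ``oxo_error_rate`` is
    the per-base probability of an 8-oxoG-like G>T / C>A artifact on a
    fragment, independent of age.
    """

    sample_id: str
    age: float
    cohort: str
    run: str
    seed: int
    common_del_freq: float = 0.0
    major_arc_del_freq: float = 0.0
    crm_freq: float = 0.0
    crd_freq: float = 0.0
    chimera_rate: float = 0.0
    snv_rate_per_bp: float = 0.0
    change_weights: dict = field(default_factory=lambda: dict(DEFAULT_CHANGE_WEIGHTS))
    control_region_multiplier: float = 5.0
    hotspot_3243_freq: float = 0.0
    oxo_error_rate: float = 0.0
    coverage_target: float = 1000.0
    # library nuisance parameters (typical TruSeq-like values; stated, not fitted)
    read_length: int = 100
    insert_mean: float = 300.0
    insert_sd: float = 50.0
    insert_bounds: tuple[int, int] = (150, 600)
    qual_mean: float = 35.0
    qual_sd: float = 2.5
    qual_floor: int = 20
    qual_cap: int = 41
    error_model: str = "quality"  # "quality" or "none"
    crm_unit_range: tuple[int, int] = (44, 87)
    crm_target_length: int = 2000
    crd_prototype_fraction: float = 0.90
    major_arc_repeat_fraction: float = 0.80

    def validate(self) -> None:
        freqs = {
            "common_del_freq": self.common_del_freq,
            "major_arc_del_freq": self.major_arc_del_freq,
            "crm_freq": self.crm_freq,
            "crd_freq": self.crd_freq,
        }
        for name, f in freqs.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"{name}={f} outside [0, 1]")
        if self.common_del_freq + self.major_arc_del_freq + self.crd_freq > 1.0:
            raise ValueError("rearrangement frequencies exceed 1 (one per molecule)")
        if self.coverage_target <= 0:
            raise ValueError("coverage_target must be positive")
        w = sum(self.change_weights.values())
        if abs(w - 1.0) > 1e-6:
            raise ValueError(f"change weights sum to {w}, expected 1")


@dataclass
class Haplotype:
    """One distinct molecule structure (shared by all its copies).

    ``segments`` are 0-based half-open reference intervals concatenated to
    form the (circular) molecule.  ``junction`` is the non-overlapping
    (b5, b3) junction in 1-based reference coordinates, or None for the
    unrearranged haplotype.  For CRMs, ``unit_length`` is the tandem unit
    size and every unit boundary is a junction.
    """

    cls: str
    segments: tuple[tuple[int, int], ...]
    junction: tuple[int, int] | None = None
    unit_length: int | None = None

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.segments)

    def codes(self, ref_codes: np.ndarray) -> np.ndarray:
        return np.concatenate([ref_codes[s:e] for s, e in self.segments])

    def junction_offsets(self) -> np.ndarray:
        """Molecule offsets at which a new segment (junction) starts."""
        if self.cls == "reference":
            return np.empty(0, dtype=np.int64)
        if self.cls == "crm":
            u = self.unit_length
            return np.arange(0, self.length, u, dtype=np.int64)
        # single deletion junction: molecule resumes at offset = len(seg1)
        return np.array([self.segments[0][1] - self.segments[0][0]], dtype=np.int64)

    def offset_of(self, pos: int) -> int | None:
        """Molecule offset of 1-based reference position, None if deleted."""
        p0 = pos - 1
        off = 0
        for s, e in self.segments:
            if s <= p0 < e:
                return off + (p0 - s)
            off += e - s
        return None


@dataclass
class MoleculeSet:
    """A population of molecules with per-molecule truth."""

    genome: CircularGenome
    haplotypes: list[Haplotype]
    hap_of_mol: np.ndarray  # int32 (n_molecules,)
    snv_mol: np.ndarray  # int64 molecule index per planted SNV
    snv_pos: np.ndarray  # int64 1-based reference position
    snv_code: np.ndarray  # uint8 new base code

    @property
    def n_molecules(self) -> int:
        return len(self.hap_of_mol)

    @property
    def lengths(self) -> np.ndarray:
        hl = np.array([h.length for h in self.haplotypes])
        return hl[self.hap_of_mol]

    @property
    def classes(self) -> np.ndarray:
        hc = np.array([h.cls for h in self.haplotypes], dtype=object)
        return hc[self.hap_of_mol]

    def genome_equivalents(self) -> float:
        return float(self.lengths.sum()) / self.genome.L

    def realized_truth(self) -> pd.DataFrame:
        """Per-class realized molecule fractions and junction burdens."""
        classes = self.classes
        ge = self.genome_equivalents()
        rows = []
        for cls in CLASSES:
            sel = np.flatnonzero(classes == cls)
            njunc = sum(
                len(self.haplotypes[h].junction_offsets()) for h in self.hap_of_mol[sel]
            )
            rows.append(
                {
                    "class": cls,
                    "n_molecules": len(sel),
                    "molecule_fraction": len(sel) / self.n_molecules,
                    "junctions": njunc,
                    "junction_burden": njunc / ge,
                }
            )
        return pd.DataFrame(rows)

    def detectable_junction_burden(
        self,
        read_length: int = 100,
        min_segment: int = 15,
        slack: int = 3,
    ) -> dict[str, float]:
        """Expected callable-junction burden per class, per genome equivalent.

        A split-read caller sees a junction only from read placements that
        leave ``min_segment`` bases on both sides (and, in tandem arrays,
        whose neighbouring junctions fall within ``slack`` of the read
        ends).  This weights each planted junction by that detection
        aperture; multiplied by average coverage it is the expected
        called-junction count for the class.
        """
        from .rearrange import junction_aperture

        ge = self.genome_equivalents()
        out: dict[str, float] = {}
        for cls in CLASSES:
            total = 0.0
            for h in self.hap_of_mol[np.flatnonzero(self.classes == cls)]:
                hap = self.haplotypes[h]
                n_j = len(hap.junction_offsets())
                ap = junction_aperture(
                    hap.unit_length, read_length, min_segment, slack
                )
                total += n_j * ap / read_length
            out[cls] = total / ge
        return out

    def snv_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"molecule": self.snv_mol, "pos": self.snv_pos, "new_code": self.snv_code}
        )


def find_repeat_pairs(
    genome: CircularGenome,
    word: int = 8,
    window: tuple[int, int] = MAJOR_ARC_WINDOW,
    span_range: tuple[int, int] = (400, 9500),
    cap: int = 4000,
) -> list[tuple[int, int, int]]:
    """Direct-repeat pairs (left_start, right_start, repeat_len) in a window.

    Scans exact ``word``-mers within the (non-wrapping) window and extends
    each co-occurring pair to its maximal perfect repeat.  Used to plant
    repeat-associated major-arc deletions.
    """
    lo, hi = window
    seq = genome.sequence
    occ: dict[str, list[int]] = {}
    for p in range(lo, hi - word + 2):  # 1-based starts
        occ.setdefault(seq[p - 1 : p - 1 + word], []).append(p)
    pairs = []
    for positions in occ.values():
        if len(positions) < 2:
            continue
        for i in range(len(positions) - 1):
            for j in range(i + 1, min(len(positions), i + 4)):
                p, q = positions[i], positions[j]
                if not span_range[0] <= q - p <= span_range[1]:
                    continue
                # extend to maximal repeat
                ext = word
                while q + ext <= hi and seq[p - 1 + ext] == seq[q - 1 + ext]:
                    ext += 1
                back = 0
                while p - back - 1 >= lo and seq[p - back - 2] == seq[q - back - 2]:
                    back += 1
                pairs.append((p - back, q - back, ext + back))
                if len(pairs) >= cap:
                    return pairs
    return pairs


def _crm_window_positions(L: int) -> np.ndarray:
    lo, hi = CRM_WINDOW
    return np.concatenate([np.arange(lo, L + 1), np.arange(1, hi + 1)])


def build_molecule_population(
    genome: CircularGenome,
    truth: SampleTruth,
    n_molecules: int = 20000,
    rng: np.random.Generator | None = None,
) -> MoleculeSet:
    """Draw a molecule population realizing the configured frequencies."""
    truth.validate()
    rng = rng or np.random.default_rng(truth.seed)
    L = genome.L

    for name, f in (
        ("common_del_freq", truth.common_del_freq),
        ("major_arc_del_freq", truth.major_arc_del_freq),
        ("crd_freq", truth.crd_freq),
    ):
        if 0 < f and f * n_molecules < 1:
            raise ValueError(
                f"{name}={f} cannot be realized with {n_molecules} molecules"
            )

    haplotypes = [Haplotype("reference", ((0, L),))]
    hap_of_mol = np.zeros(n_molecules, dtype=np.int32)

    def add_hap(h: Haplotype) -> int:
        haplotypes.append(h)
        return len(haplotypes) - 1

    def deletion_hap(cls: str, b5: int, b3: int) -> Haplotype:
        return Haplotype(cls, ((0, b5), (b3 - 1, L)), junction=(b5, b3))

    # class per molecule (at most one rearrangement each)
    p_ref = 1.0 - truth.common_del_freq - truth.major_arc_del_freq - truth.crd_freq
    draw = rng.choice(
        4,
        size=n_molecules,
        p=[p_ref, truth.common_del_freq, truth.major_arc_del_freq, truth.crd_freq],
    )

    common_hap = None
    for i in np.flatnonzero(draw == 1):
        if common_hap is None:
            b5, b3 = COMMON_DELETION_JUNCTION
            common_hap = add_hap(deletion_hap("common_deletion", b5, b3))
        hap_of_mol[i] = common_hap

    major_idx = np.flatnonzero(draw == 2)
    if len(major_idx):
        repeat_pairs = find_repeat_pairs(genome)
        lo, hi = MAJOR_ARC_WINDOW
        for i in major_idx:
            if repeat_pairs and rng.random() < truth.major_arc_repeat_fraction:
                lp, rp, k = repeat_pairs[rng.integers(len(repeat_pairs))]
                # delete between the repeats, keeping the left copy: the
                # deleted stretch ends with the right copy
                b5, b3 = lp + k - 1, rp + k
            else:
                while True:
                    b5 = int(rng.integers(lo, hi - 400))
                    b3 = int(rng.integers(b5 + 401, hi + 1))
                    if b3 <= hi:
                        break
            hap_of_mol[i] = add_hap(deletion_hap("major_arc", b5, b3))

    crd_idx = np.flatnonzero(draw == 3)
    if len(crd_idx):
        proto = None
        for i in crd_idx:
            if rng.random() < truth.crd_prototype_fraction:
                if proto is None:
                    b5, b3 = CRD_PROTOTYPE_JUNCTION
                    proto = add_hap(deletion_hap("crd", b5, b3))
                hap_of_mol[i] = proto
            else:
                b5 = int(rng.integers(250, 430))
                dlen = int(rng.integers(40, 67))
                b3 = min(b5 + dlen + 1, 495)
                hap_of_mol[i] = add_hap(deletion_hap("crd", b5, b3))

    # CRMs: circular tandem arrays; draw molecules until the requested
    # junction burden (junctions per genome equivalent) is reached.
    if truth.crm_freq > 0:
        target_junctions = truth.crm_freq * n_molecules
        if target_junctions < 2:
            raise ValueError(
                f"crm_freq={truth.crm_freq} cannot be realized with "
                f"{n_molecules} molecules"
            )
        wpos = _crm_window_positions(L)
        ref_idx = np.flatnonzero(hap_of_mol == 0)
        got = 0.0
        k_used = 0
        while got < target_junctions and k_used < len(ref_idx):
            u = int(rng.integers(truth.crm_unit_range[0], truth.crm_unit_range[1] + 1))
            start_i = int(rng.integers(0, len(wpos) - u + 1))
            us = int(wpos[start_i])  # 1-based unit start
            copies = max(2, round(truth.crm_target_length / u))
            # unit as reference segments (may wrap the origin)
            ue = us + u - 1  # may exceed L
            if ue <= L:
                seg = [(us - 1, ue)]
            else:
                seg = [(us - 1, L), (0, ue - L)]
            h = Haplotype(
                "crm",
                tuple(seg * copies),
                junction=(wrap_pos(ue, L), us),
                unit_length=u,
            )
            mol = ref_idx[k_used]
            hap_of_mol[mol] = add_hap(h)
            got += copies
            k_used += 1

    mols = MoleculeSet(
        genome=genome,
        haplotypes=haplotypes,
        hap_of_mol=hap_of_mol,
        snv_mol=np.empty(0, dtype=np.int64),
        snv_pos=np.empty(0, dtype=np.int64),
        snv_code=np.empty(0, dtype=np.uint8),
    )
    _plant_snvs(mols, truth, rng)
    return mols


def _position_weights(genome: CircularGenome, truth: SampleTruth):
    """Per-base-change sampling arrays honoring the control-region excess."""
    from .reference import rcrs_annotation

    L = genome.L
    try:
        if L == 16569:
            annot = rcrs_annotation()
            is_control = annot._is_control[1:]
        else:
            raise ValueError
    except Exception:
        # synthetic references: treat the last ~7% of the circle as control
        is_control = np.zeros(L, dtype=bool)
        is_control[int(L * 0.93):] = True
    mult = np.where(is_control, truth.control_region_multiplier, 1.0)
    out = {}
    for b, code in zip("ACGT", range(4)):
        pos = np.flatnonzero(genome.codes == code) + 1
        w = mult[pos - 1]
        out[b] = (pos, w / w.sum())
    return out


def _plant_snvs(mols: MoleculeSet, truth: SampleTruth, rng: np.random.Generator) -> None:
    genome = mols.genome
    L = genome.L
    lengths = mols.lengths
    classes = mols.classes
    plantable = classes != "crm"  # CRM arrays carry no planted point mutations

    snv_mol: list[int] = []
    snv_pos: list[int] = []
    snv_code: list[int] = []

    if truth.snv_rate_per_bp > 0:
        weights = _position_weights(genome, truth)
        lam = truth.snv_rate_per_bp * lengths * plantable
        counts = rng.poisson(lam)
        change_p = np.array([truth.change_weights[c] for c in BASE_CHANGES])
        code_of = {b: i for i, b in enumerate("ACGT")}
        total = int(counts.sum())
        if total:
            mol_ids = np.repeat(np.arange(mols.n_molecules), counts)
            changes = rng.choice(len(BASE_CHANGES), size=total, p=change_p)
            for ci, change in enumerate(BASE_CHANGES):
                sel = np.flatnonzero(changes == ci)
                if not len(sel):
                    continue
                src, dst = change[0], change[2]
                pos_arr, w = weights[src]
                picks = rng.choice(len(pos_arr), size=len(sel), p=w)
                for m, p in zip(mol_ids[sel], pos_arr[picks]):
                    hap = mols.haplotypes[mols.hap_of_mol[m]]
                    if hap.cls != "reference" and hap.offset_of(int(p)) is None:
                        continue  # fell in a deleted stretch; drop
                    snv_mol.append(int(m))
                    snv_pos.append(int(p))
                    snv_code.append(code_of[dst])

    if truth.hotspot_3243_freq > 0 and L >= 3243:
        carriers = np.flatnonzero(
            (rng.random(mols.n_molecules) < truth.hotspot_3243_freq) & plantable
        )
        for m in carriers:
            snv_mol.append(int(m))
            snv_pos.append(3243)
            snv_code.append(2)  # G

    mols.snv_mol = np.array(snv_mol, dtype=np.int64)
    mols.snv_pos = np.array(snv_pos, dtype=np.int64)
    mols.snv_code = np.array(snv_code, dtype=np.uint8)


@dataclass
class ReadPairSet:
    """Paired reads with per-base qualities and a read-level truth table.

    ``seq1``/``seq2`` are (n_fragments, read_length) uint8 code matrices in
    sequencing orientation (mate 2 is the reverse complement of the
    fragment end); ``fragments`` records the source molecule of every pair
    and ``junction_reads`` every planted junction a read spans.  Reads are
    mate-interleaved when flattened: read 2i is mate 1 of fragment i.
    """

    sample_id: str
    seq1: np.ndarray
    seq2: np.ndarray
    qual1: np.ndarray
    qual2: np.ndarray
    fragments: pd.DataFrame
    junction_reads: pd.DataFrame

    @property
    def n_pairs(self) -> int:
        return len(self.seq1)

    @property
    def read_length(self) -> int:
        return self.seq1.shape[1]

    def reads(self) -> np.ndarray:
        """Mate-interleaved (2n, read_length) read matrix."""
        n, rl = self.seq1.shape
        out = np.empty((2 * n, rl), dtype=np.uint8)
        out[0::2] = self.seq1
        out[1::2] = self.seq2
        return out

    def quals(self) -> np.ndarray:
        n, rl = self.qual1.shape
        out = np.empty((2 * n, rl), dtype=np.int8)
        out[0::2] = self.qual1
        out[1::2] = self.qual2
        return out

    def read_id(self, read_index: int) -> str:
        return f"{self.sample_id}:{read_index // 2}/{read_index % 2 + 1}"

    def to_fastq(self, path1, path2) -> None:
        from .reference import decode_seq

        with open(path1, "w") as f1, open(path2, "w") as f2:
            for i in range(self.n_pairs):
                for mate, (seqs, quals, fh) in enumerate(
                    ((self.seq1, self.qual1, f1), (self.seq2, self.qual2, f2))
                ):
                    s = decode_seq(seqs[i])
                    q = "".join(chr(q + 33) for q in quals[i])
                    fh.write(f"@{self.sample_id}:{i}/{mate + 1}\n{s}\n+\n{q}\n")


def simulate_reads(
    mols: MoleculeSet,
    truth: SampleTruth,
    rng: np.random.Generator | None = None,
) -> ReadPairSet:
    """Sample paired-end reads from a molecule population."""
    rng = rng or np.random.default_rng(truth.seed + 1)
    genome = mols.genome
    L = genome.L
    rl = truth.read_length
    lengths = mols.lengths
    n_frags = int(round(truth.coverage_target * L / (2 * rl)))

    p = lengths / lengths.sum()
    mol_of_frag = rng.choice(mols.n_molecules, size=n_frags, p=p)
    flen = np.clip(
        np.round(rng.normal(truth.insert_mean, truth.insert_sd, n_frags)),
        max(truth.insert_bounds[0], rl),
        truth.insert_bounds[1],
    ).astype(np.int64)
    mlen = lengths[mol_of_frag]
    start = (rng.random(n_frags) * mlen).astype(np.int64)

    m1 = np.empty((n_frags, rl), dtype=np.uint8)
    m2f = np.empty((n_frags, rl), dtype=np.uint8)  # mate 2, fragment orientation
    ref_codes = genome.codes

    # molecule SNVs grouped for fragment application
    order = np.argsort(mol_of_frag, kind="stable")
    bounds = np.searchsorted(mol_of_frag[order], np.arange(mols.n_molecules + 1))

    junc_rows: list[tuple] = []
    arange_rl = np.arange(rl)
    hap_codes_cache: dict[int, np.ndarray] = {}

    for hap_id, hap in enumerate(mols.haplotypes):
        mol_sel = np.flatnonzero(mols.hap_of_mol == hap_id)
        if not len(mol_sel):
            continue
        if len(mol_sel) == mols.n_molecules:
            frag_sel = np.arange(n_frags)
        else:
            frag_sel = np.concatenate(
                [order[bounds[m] : bounds[m + 1]] for m in mol_sel]
            )
        if not len(frag_sel):
            continue
        if hap_id not in hap_codes_cache:
            codes = hap.codes(ref_codes) if hap_id else ref_codes
            hap_codes_cache[hap_id] = np.concatenate([codes, codes, codes[:rl]])
        dbl = hap_codes_cache[hap_id]
        hlen = hap.length
        st = start[frag_sel]
        fl = flen[frag_sel]
        m1[frag_sel] = dbl[st[:, None] + arange_rl[None, :]]
        st2 = (st + fl - rl) % hlen
        m2f[frag_sel] = dbl[st2[:, None] + arange_rl[None, :]]

        # read-level junction truth
        joff = hap.junction_offsets()
        if len(joff):
            b5, b3 = hap.junction
            u = hap.unit_length
            for mate, st_m in ((1, st), (2, st2)):
                if hap.cls == "crm":
                    d = (-st_m) % u
                    span = d < rl  # first junction offset in read (may be 0)
                    d = np.where(d == 0, u, d)  # offset 0 junction: next one
                    span = (d >= 1) & (d <= rl - 1)
                else:
                    d = (joff[0] - st_m) % hlen
                    span = (d >= 1) & (d <= rl - 1)
                for f, off in zip(frag_sel[span], d[span]):
                    junc_rows.append(
                        (2 * int(f) + mate - 1, hap.cls, b5, b3, int(off), False)
                    )

    # planted SNVs onto overlapping fragments
    if len(mols.snv_mol):
        hap_offsets: dict[tuple[int, int], int | None] = {}
        for m, pos, code in zip(mols.snv_mol, mols.snv_pos, mols.snv_code):
            frags = order[bounds[m] : bounds[m + 1]]
            if not len(frags):
                continue
            hap_id = int(mols.hap_of_mol[m])
            key = (hap_id, int(pos))
            if key not in hap_offsets:
                hap = mols.haplotypes[hap_id]
                hap_offsets[key] = (
                    int(pos) - 1 if hap_id == 0 else hap.offset_of(int(pos))
                )
            off = hap_offsets[key]
            if off is None:
                continue
            hlen = mols.haplotypes[hap_id].length
            d1 = (off - start[frags]) % hlen
            hit1 = d1 < rl
            m1[frags[hit1], d1[hit1]] = code
            st2 = (start[frags] + flen[frags] - rl) % hlen
            d2 = (off - st2) % hlen
            hit2 = d2 < rl
            m2f[frags[hit2], d2[hit2]] = code

    # library chimeras: replace a fragment by a same-sense join of two
    # random fragments; the junction falls anywhere in the fragment
    n_chim = rng.binomial(n_frags, truth.chimera_rate) if truth.chimera_rate else 0
    if n_chim:
        chim = rng.choice(n_frags, size=n_chim, replace=False)
        for f in chim:
            fl = int(flen[f])
            cut = int(rng.integers(30, fl - 30)) if fl > 60 else fl // 2
            picks = []
            for seg_len in (cut, fl - cut):
                mol = int(rng.choice(mols.n_molecules, p=p))
                hap_id = int(mols.hap_of_mol[mol])
                if hap_id not in hap_codes_cache:
                    codes = mols.haplotypes[hap_id].codes(ref_codes) if hap_id else ref_codes
                    hap_codes_cache[hap_id] = np.concatenate([codes, codes, codes[:rl]])
                hlen = mols.haplotypes[hap_id].length
                s0 = int(rng.integers(0, hlen))
                picks.append((hap_id, s0, seg_len))
            frag = np.concatenate(
                [hap_codes_cache[h][s0 : s0 + sl] for h, s0, sl in picks]
            )
            m1[f] = frag[:rl]
            m2f[f] = frag[fl - rl :]
            # junction truth for chimeric reads (reference-coordinate ends
            # only meaningful for reference-haplotype segments)
            h1, s1, sl1 = picks[0]
            h2, s2, _ = picks[1]
            if h1 == 0 and h2 == 0:
                b5c = wrap_pos(s1 + sl1, L)
                b3c = wrap_pos(s2 + 1, L)
                if 1 <= cut <= rl - 1:
                    junc_rows.append((2 * int(f), "chimera", b5c, b3c, cut, True))
                d2 = cut - (fl - rl)
                if 1 <= d2 <= rl - 1:
                    junc_rows.append((2 * int(f) + 1, "chimera", b5c, b3c, d2, True))

    # 8-oxoG-like artifacts: G>T (and C>A for the opposing strand) on the
    # fragment before amplification
    if truth.oxo_error_rate > 0:
        for mat in (m1, m2f):
            mask = rng.random(mat.shape) < truth.oxo_error_rate
            mat[mask & (mat == 2)] = 3  # G>T
            mask2 = rng.random(mat.shape) < truth.oxo_error_rate
            mat[mask2 & (mat == 1)] = 0  # C>A

    m2 = revcomp_codes(m2f)

    qual1 = np.clip(
        np.round(rng.normal(truth.qual_mean, truth.qual_sd, (n_frags, rl))),
        truth.qual_floor,
        truth.qual_cap,
    ).astype(np.int8)
    qual2 = np.clip(
        np.round(rng.normal(truth.qual_mean, truth.qual_sd, (n_frags, rl))),
        truth.qual_floor,
        truth.qual_cap,
    ).astype(np.int8)

    if truth.error_model == "quality":
        for mat, q in ((m1, qual1), (m2, qual2)):
            perr = 10.0 ** (-q.astype(np.float64) / 10.0)
            mask = (rng.random(mat.shape) < perr) & (mat < 4)
            n_err = int(mask.sum())
            if n_err:
                mat[mask] = (mat[mask] + rng.integers(1, 4, n_err)) % 4
    elif truth.error_model != "none":
        raise ValueError(f"unknown error_model {truth.error_model!r}")

    fragments = pd.DataFrame(
        {
            "molecule": mol_of_frag,
            "haplotype": mols.hap_of_mol[mol_of_frag],
            "class": mols.classes[mol_of_frag],
            "start": start,
            "insert": flen,
        }
    )
    if n_chim:
        fragments["chimera"] = False
        fragments.loc[chim, "chimera"] = True
    else:
        fragments["chimera"] = False
    junction_reads = pd.DataFrame(
        junc_rows,
        columns=["read_index", "class", "b5_crs", "b3_crs", "read_offset", "chimera"],
    )
    return ReadPairSet(
        sample_id=truth.sample_id,
        seq1=m1,
        seq2=m2,
        qual1=qual1,
        qual2=qual2,
        fragments=fragments,
        junction_reads=junction_reads,
    )


@dataclass
class CohortConfig:
    """Cohort-level generating model: linear age accumulation per feature.

    Loads are ``value_at_25 + slope x (age - 25)`` clamped at zero; SNV
    rates are anchored, ``baseline + slope x age``.  Default coefficients
    are the putamen rates of the accumulation models this package
    reproduces.
    """

    ages: tuple[float, ...] = (20, 25, 34, 70, 78, 85)
    young_max_age: float = 50.0
    seed: int = 1
    coverage_target: float = 1000.0
    n_molecules: int = 20000
    common_slope: float = 3.35e-5
    common_at_25: float = 0.16e-3
    major_arc_slope: float = 22.36e-5
    major_arc_at_25: float = 4.71e-3
    major_arc_cap: float = 1.0
    crm_level: float = 8e-3  # no age association
    crd_slope: float = 1.2e-4
    crd_at_25: float = 5e-4
    snv_slope: float = 4.02e-7
    snv_baseline: float = 0.37e-5
    hotspot_slope: float = 5e-5
    hotspot_at_25: float = 2e-4
    chimera_rate: float = 1e-3
    oxo_error_rate: float = 2e-5
    error_model: str = "quality"
    runs: tuple[str, ...] = ("run1", "run2")

    def truth_for(self, i: int, age: float) -> SampleTruth:
        def load(value25: float, slope: float) -> float:
            v = value25 + slope * (age - 25)
            if v < 0:
                logger.warning(
                    "negative computed load at age %s (value25=%g slope=%g); clamped to 0",
                    age, value25, slope,
                )
                return 0.0
            return v

        cohort = "young" if age <= self.young_max_age else "aged"
        return SampleTruth(
            sample_id=f"S{i:02d}",
            age=age,
            cohort=cohort,
            run=self.runs[i % len(self.runs)],
            seed=self.seed * 10_000 + i,
            common_del_freq=load(self.common_at_25, self.common_slope),
            major_arc_del_freq=min(
                load(self.major_arc_at_25, self.major_arc_slope), self.major_arc_cap
            ),
            crm_freq=self.crm_level,
            crd_freq=load(self.crd_at_25, self.crd_slope),
            chimera_rate=self.chimera_rate,
            snv_rate_per_bp=self.snv_baseline + self.snv_slope * age,
            hotspot_3243_freq=load(self.hotspot_at_25, self.hotspot_slope),
            oxo_error_rate=self.oxo_error_rate,
            coverage_target=self.coverage_target,
            error_model=self.error_model,
        )

    def truths(self) -> list[SampleTruth]:
        if len(set(self.ages)) < 2:
            raise ValueError("cohort needs at least two distinct ages")
        return [self.truth_for(i, a) for i, a in enumerate(self.ages)]


def generate_cohort(
    config: CohortConfig, genome: CircularGenome
) -> list[tuple[SampleTruth, MoleculeSet, ReadPairSet]]:
    """Simulate every specimen of a cohort; returns truth + reads per sample."""
    out = []
    for truth in config.truths():
        rng = np.random.default_rng(truth.seed)
        mols = build_molecule_population(genome, truth, config.n_molecules, rng)
        reads = simulate_reads(mols, truth, rng)
        out.append((truth, mols, reads))
    return out
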