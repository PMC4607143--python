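"""Readers and writers for the pipeline's text formats.

Supported genotype dialects:

* ``wide_csv`` — rows are samples, two columns per locus named
  ``<locus_id>_a`` / ``<locus_id>_b``; missing cells empty, ``.`` or ``./.``.
* ``pedmap`` — PLINK text PED/MAP pair (biallelic loci only, ``0`` missing).
* ``vcf`` — VCF 4.x via cyvcf2; only the GT field is consumed.
* ``parentage_csv`` (write only) — one row per sample, two columns per locus,
  missing as empty cells; readable back through the wide_csv dialect.

Plus: panel definition CSV, pileup summary TSV, pedigree registry CSV and
sample-record CSV.
"""

from __future__ import annotations

import os
import warnings

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, SampleRecord
from .panel import Amplicon, AmpliconPanel, Locus, PileupSite
from .pedigree import PedigreeEntry, PedigreeRegistry

MISSING_TOKENS = {"", ".", "./.", "0", "NA", "nan", "None"}


class ParseError(ValueError):
    pass


class DuplicateSampleError(ParseError):
    pass


# ---------------------------------------------------------------------------
# panel
# ---------------------------------------------------------------------------

def read_panel_csv(path) -> AmpliconPanel:
    """Panel definition CSV: locus_id, amplicon_id, chrom, pos, ref, alt, target_class.

    ``alt`` may hold several alleles joined by ``;`` for multi-allelic markers.
    """
    df = pd.read_csv(path, dtype=str, comment="#")
    required = {"locus_id", "amplicon_id", "chrom", "pos", "ref", "alt", "target_class"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise ParseError(f"{path}: panel CSV missing columns {sorted(missing_cols)}")
    amps: dict[str, list[Locus]] = {}
    classes: dict[str, str] = {}
    order: list[str] = []
    for line_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            locus = Locus(
                locus_id=row.locus_id,
                amplicon_id=row.amplicon_id,
                chromosome=row.chrom,
                position=int(row.pos),
                ref_allele=row.ref,
                alt_alleles=tuple(str(row.alt).split(";")),
            )
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}, line {line_no}: {exc}") from exc
        if row.amplicon_id not in amps:
            amps[row.amplicon_id] = []
            classes[row.amplicon_id] = row.target_class
            order.append(row.amplicon_id)
        amps[row.amplicon_id].append(locus)
    return AmpliconPanel([Amplicon(a, classes[a], amps[a]) for a in order])


def write_panel_csv(panel: AmpliconPanel, path) -> None:
    rows = []
    for amp in panel.amplicons:
        for l in amp.loci:
            rows.append({
                "locus_id": l.locus_id, "amplicon_id": amp.amplicon_id,
                "chrom": l.chromosome, "pos": l.position, "ref": l.ref_allele,
                "alt": ";".join(l.alt_alleles), "target_class": amp.target_class,
            })
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def read_genotypes(path, format: str, panel: AmpliconPanel) -> GenotypeMatrix:
    """Read genotypes and align them to the panel.

    Every panel locus is present in the result (an all-missing column when the
    file lacks it); loci in the file unknown to the panel are dropped with a
    warning; allele coding is normalised to the panel's ref/alt order.
    """
    if format == "wide_csv":
        return _read_wide_csv(path, panel)
    if format == "pedmap":
        return _read_pedmap(path, panel)
    if format == "vcf":
        return _read_vcf(path, panel)
    raise ValueError(f"unknown genotype format {format!r}")


def _finalise(samples, panel, found_cols, found_pairs, path, unknown) -> GenotypeMatrix:
    if unknown:
        warnings.warn(
            f"{path}: {len(unknown)} loci not in panel dropped: "
            f"{sorted(unknown)[:5]}{'...' if len(unknown) > 5 else ''}"
        )
    loci = panel.loci
    pairs = np.full((len(samples), len(loci), 2), -1, dtype=np.int16)
    idx = {l.locus_id: j for j, l in enumerate(loci)}
    for locus_id, col in zip(found_cols, found_pairs):
        pairs[:, idx[locus_id], :] = col
    return GenotypeMatrix(samples, loci, pairs)


def _alleles_to_pair(a: str, b: str, locus: Locus, where: str) -> tuple[int, int]:
    miss_a = a in MISSING_TOKENS
    miss_b = b in MISSING_TOKENS
    if miss_a and miss_b:
        return (-1, -1)
    if miss_a or miss_b:
        warnings.warn(f"{where}: half-typed call coerced to MISSING")
        return (-1, -1)
    try:
        ia, ib = locus.alleles.index(a), locus.alleles.index(b)
    except ValueError:
        raise ParseError(
            f"{where}: allele pair ({a},{b}) outside declared alleles "
            f"{locus.alleles} for locus {locus.locus_id}"
        ) from None
    return (min(ia, ib), max(ia, ib))


def _read_wide_csv(path, panel: AmpliconPanel) -> GenotypeMatrix:
    df = pd.read_csv(path, dtype=str, keep_default_na=False, comment="#")
    if df.columns[0] != "sample_id":
        raise ParseError(f"{path}: first column must be 'sample_id'")
    samples = df["sample_id"].tolist()
    dupes = df["sample_id"][df["sample_id"].duplicated()].tolist()
    if dupes:
        raise DuplicateSampleError(f"{path}: duplicate sample ids {sorted(set(dupes))}")
    locus_cols: dict[str, list[str]] = {}
    unknown = set()
    for col in df.columns[1:]:
        if not (col.endswith("_a") or col.endswith("_b")):
            raise ParseError(f"{path}: genotype column {col!r} must end in _a or _b")
        locus_id = col[:-2]
        if locus_id not in panel:
            unknown.add(locus_id)
            continue
        locus_cols.setdefault(locus_id, []).append(col)
    found_cols, found_pairs = [], []
    for locus_id, cols in locus_cols.items():
        if len(cols) != 2:
            raise ParseError(f"{path}: locus {locus_id} needs both _a and _b columns")
        locus = panel.get_locus(locus_id)
        col = np.full((len(samples), 2), -1, dtype=np.int16)
        a_col = df[f"{locus_id}_a"].tolist()
        b_col = df[f"{locus_id}_b"].tolist()
        for i, (a, b) in enumerate(zip(a_col, b_col)):
            col[i] = _alleles_to_pair(
                a.strip(), b.strip(), locus, f"{path}, row {i + 2}, locus {locus_id}"
            )
        found_cols.append(locus_id)
        found_pairs.append(col)
    return _finalise(samples, panel, found_cols, found_pairs, path, unknown)


def _read_pedmap(path, panel: AmpliconPanel) -> GenotypeMatrix:
    """PLINK text PED/MAP pair. ``path`` may point at either file or the stem."""
    stem, ext = os.path.splitext(str(path))
    if ext not in (".ped", ".map"):
        stem = str(path)
    ped_path, map_path = stem + ".ped", stem + ".map"
    map_loci: list[Locus | None] = []
    unknown = set()
    with open(map_path) as fh:
        for line_no, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 4:
                raise ParseError(f"{map_path}, line {line_no}: expected 4 columns")
            chrom, locus_id, _cm, pos = fields
            locus = (panel.get_locus(locus_id) if locus_id in panel
                     else panel.locus_at(chrom, int(pos)))
            if locus is None:
                unknown.add(locus_id)
            map_loci.append(locus)
    samples: list[str] = []
    rows: list[np.ndarray] = []
    with open(ped_path) as fh:
        for line_no, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + 2 * len(map_loci):
                raise ParseError(
                    f"{ped_path}, line {line_no}: expected {6 + 2 * len(map_loci)} "
                    f"columns, got {len(fields)}"
                )
            sample_id = fields[1]
            if sample_id in samples:
                raise DuplicateSampleError(f"{ped_path}: duplicate sample {sample_id}")
            samples.append(sample_id)
            row = np.full((len(map_loci), 2), -1, dtype=np.int16)
            for j, locus in enumerate(map_loci):
                if locus is None:
                    continue
                a, b = fields[6 + 2 * j], fields[7 + 2 * j]
                row[j] = _alleles_to_pair(a, b, locus,
                                          f"{ped_path}, line {line_no}, locus {locus.locus_id}")
            rows.append(row)
    found_cols, found_pairs = [], []
    for j, locus in enumerate(map_loci):
        if locus is None:
            continue
        found_cols.append(locus.locus_id)
        found_pairs.append(np.array([r[j] for r in rows], dtype=np.int16)
                           if rows else np.empty((0, 2), dtype=np.int16))
    return _finalise(samples, panel, found_cols, found_pairs, ped_path, unknown)


def _read_vcf(path, panel: AmpliconPanel) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if len(set(samples)) != len(samples):
        raise DuplicateSampleError(f"{path}: duplicate sample ids in VCF header")
    found_cols, found_pairs, unknown = [], [], set()
    for variant in vcf:
        locus = None
        if variant.ID and variant.ID in panel:
            locus = panel.get_locus(variant.ID)
        if locus is None:
            locus = panel.locus_at(variant.CHROM, variant.POS)
        if locus is None:
            unknown.add(variant.ID or f"{variant.CHROM}:{variant.POS}")
            continue
        vcf_alleles = [variant.REF] + list(variant.ALT)
        try:
            remap = [locus.alleles.index(a) for a in vcf_alleles]
        except ValueError:
            raise ParseError(
                f"{path}: {locus.locus_id} VCF alleles {vcf_alleles} do not match "
                f"panel alleles {locus.alleles}"
            ) from None
        col = np.full((len(samples), 2), -1, dtype=np.int16)
        for i, gt in enumerate(variant.genotypes):
            a, b = gt[0], gt[1]
            if a < 0 or b < 0:
                if a >= 0 or b >= 0:
                    warnings.warn(f"{path}: half-typed call coerced to MISSING "
                                  f"({samples[i]} at {locus.locus_id})")
                continue
            ia, ib = remap[a], remap[b]
            col[i] = (min(ia, ib), max(ia, ib))
        found_cols.append(locus.locus_id)
        found_pairs.append(col)
    return _finalise(samples, panel, found_cols, found_pairs, path, unknown)


def write_genotypes(matrix: GenotypeMatrix, path, format: str) -> None:
    if format == "wide_csv":
        _write_wide(matrix, path, missing_token=".")
    elif format == "parentage_csv":
        _write_wide(matrix, path, missing_token="")
    elif format == "pedmap":
        _write_pedmap(matrix, path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")


def _write_wide(matrix: GenotypeMatrix, path, missing_token: str) -> None:
    data: dict[str, list] = {"sample_id": matrix.samples}
    for j, locus in enumerate(matrix.loci):
        col = matrix.pairs[:, j, :]
        alleles = locus.alleles
        data[f"{locus.locus_id}_a"] = [
            alleles[a] if a >= 0 else missing_token for a in col[:, 0]
        ]
        data[f"{locus.locus_id}_b"] = [
            alleles[b] if b >= 0 else missing_token for b in col[:, 1]
        ]
    pd.DataFrame(data).to_csv(path, index=False)


def _write_pedmap(matrix: GenotypeMatrix, path) -> None:
    for locus in matrix.loci:
        if not locus.is_biallelic:
            raise ValueError(
                f"pedmap dialect is biallelic-only; locus {locus.locus_id} has "
                f"{locus.n_alleles} alleles"
            )
    stem, ext = os.path.splitext(str(path))
    if ext not in (".ped", ".map"):
        stem = str(path)
    with open(stem + ".map", "w") as fh:
        for locus in matrix.loci:
            fh.write(f"{locus.chromosome}\t{locus.locus_id}\t0\t{locus.position}\n")
    with open(stem + ".ped", "w") as fh:
        for i, sample in enumerate(matrix.samples):
            fields = [sample, sample, "0", "0", "0", "-9"]
            for j, locus in enumerate(matrix.loci):
                a, b = matrix.pairs[i, j]
                if a < 0:
                    fields += ["0", "0"]
                else:
                    fields += [locus.alleles[a], locus.alleles[b]]
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# pileup, registry, samples
# ---------------------------------------------------------------------------

def read_pileup_tsv(path, qmin: int = 20) -> list[PileupSite]:
    """Pileup summary TSV with columns chrom, pos, depth_q, alt_count."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"chrom", "pos", "depth_q", "alt_count"}
    if not required <= set(df.columns):
        raise ParseError(f"{path}: pileup TSV needs columns {sorted(required)}")
    sites = []
    for line_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            sites.append(PileupSite(
                chromosome=str(row.chrom), position=int(row.pos),
                depth_q=int(row.depth_q), alt_count=int(row.alt_count), qmin=qmin,
            ))
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}, line {line_no}: {exc}") from exc
    return sites


def read_registry_csv(path) -> PedigreeRegistry:
    """Registry CSV: offspring_id, known_dam, known_sire, candidate_dams,
    candidate_sires (";"-joined), facility_id."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False, comment="#")
    required = {"offspring_id", "known_dam", "known_sire",
                "candidate_dams", "candidate_sires", "facility_id"}
    if not required <= set(df.columns):
        raise ParseError(f"{path}: registry CSV needs columns {sorted(required)}")

    def split(cell: str) -> set[str]:
        cell = cell.strip()
        return set(x for x in cell.split(";") if x) if cell else set()

    entries = []
    for line_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            entries.append(PedigreeEntry(
                offspring_id=row.offspring_id,
                facility_id=row.facility_id,
                known_dam=row.known_dam or None,
                known_sire=row.known_sire or None,
                candidate_dams=split(row.candidate_dams),
                candidate_sires=split(row.candidate_sires),
            ))
        except ValueError as exc:
            raise ParseError(f"{path}, line {line_no}: {exc}") from exc
    return PedigreeRegistry(entries)


def write_registry_csv(registry: PedigreeRegistry, path) -> None:
    rows = [{
        "offspring_id": e.offspring_id,
        "known_dam": e.known_dam or "",
        "known_sire": e.known_sire or "",
        "candidate_dams": ";".join(sorted(e.candidate_dams)),
        "candidate_sires": ";".join(sorted(e.candidate_sires)),
        "facility_id": e.facility_id,
    } for e in registry]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_samples_csv(path) -> list[SampleRecord]:
    """Sample-record CSV: sample_id, sex, facility_id, roles (";"), replicate_group."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False, comment="#")
    required = {"sample_id", "sex", "facility_id", "roles", "replicate_group"}
    if not required <= set(df.columns):
        raise ParseError(f"{path}: samples CSV needs columns {sorted(required)}")
    records = []
    for line_no, row in enumerate(df.itertuples(index=False), start=2):
        try:
            records.append(SampleRecord(
                sample_id=row.sample_id,
                sex=row.sex or "unknown",
                facility_id=row.facility_id,
                role=set(x for x in row.roles.split(";") if x),
                replicate_group=row.replicate_group or None,
            ))
        except ValueError as exc:
            raise ParseError(f"{path}, line {line_no}: {exc}") from exc
    return records


def write_samples_csv(records: list[SampleRecord], path) -> None:
    rows = [{
        "sample_id": r.sample_id, "sex": r.sex, "facility_id": r.facility_id,
        "roles": ";".join(sorted(r.role)), "replicate_group": r.replicate_group or "",
    } for r in records]
    pd.DataFrame(rows).to_csv(path, index=False)
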