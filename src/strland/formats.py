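"""Readers and writers for the formats the pipeline touches.

Catalogs travel as BED6+ (0-based half-open); call sets as a flat TSV or as
VCF (1-based positions, alleles encoded as perfect-repeat expansions of the
motif to the called length so third-party VCF tools can consume them);
calibration results as a JSON sidecar. All writers are deterministic:
stable ordering and fixed float formatting to 6 significant digits.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd

from .callstats import CallSet, StrCall
from .catalog import CalibrationResult, StrLocus

_CATALOG_COLUMNS = ["chrom", "start", "end", "motif", "score", "purity", "coding"]


def _fmt(x: float) -> str:
    return f"{x:.6g}"


# ---------------------------------------------------------------------------
# catalog BED


def write_catalog(loci: list[StrLocus], path: str | Path) -> None:
    """Write a catalog as BED6+: chrom, start, end, motif, score, purity,
    coding. Input is sorted by (chrom, start) if needed (with a warning)."""
    ordered = sorted(loci, key=lambda l: (l.chrom, l.start, l.end))
    if [(l.chrom, l.start) for l in loci] != [(l.chrom, l.start) for l in ordered]:
        import warnings

        warnings.warn("catalog was unsorted; sorted by (chrom, start) on write")
    with open(path, "w") as fh:
        for l in ordered:
            fh.write(
                f"{l.chrom}\t{l.start}\t{l.end}\t{l.motif}\t{l.score}\t"
                f"{_fmt(l.purity)}\t{int(l.coding)}\n"
            )


def read_catalog(path: str | Path) -> list[StrLocus]:
    loci = []
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 7:
                raise ValueError(f"{path}:{i}: expected 7 BED columns, got {len(parts)}")
            chrom, start, end, motif, score, pur, coding = parts[:7]
            loci.append(
                StrLocus(
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    motif=motif,
                    score=int(score),
                    purity=float(pur),
                    coding=bool(int(coding)),
                )
            )
    return loci


def locus_id(locus: StrLocus) -> str:
    return f"{locus.chrom}:{locus.start}-{locus.end}"


# ---------------------------------------------------------------------------
# calls TSV


def write_calls_tsv(callset: CallSet, path: str | Path) -> None:
    rows = [
        {
            "sample": c.sample,
            "locus": c.locus,
            "alleles": ",".join(map(str, c.alleles)),
            "coverage": c.coverage,
            "supports": ",".join(map(str, c.supports)),
        }
        for c in sorted(callset.calls, key=lambda c: (c.locus, c.sample))
    ]
    pd.DataFrame(rows, columns=["sample", "locus", "alleles", "coverage", "supports"]).to_csv(
        path, sep="\t", index=False
    )


def read_calls_tsv(path: str | Path) -> CallSet:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    calls = []
    for i, row in enumerate(df.itertuples(index=False), 2):
        try:
            alleles = tuple(int(a) for a in row.alleles.split(","))
            supports = tuple(int(s) for s in row.supports.split(",")) if row.supports else ()
            calls.append(
                StrCall(
                    sample=row.sample,
                    locus=row.locus,
                    alleles=alleles,
                    coverage=int(row.coverage),
                    supports=supports,
                )
            )
        except (ValueError, AttributeError) as exc:
            raise ValueError(f"{path}: malformed record at line {i}: {exc}") from exc
    return CallSet(calls=calls)


# ---------------------------------------------------------------------------
# calls VCF


def _expand(motif: str, length: int) -> str:
    """Perfect-repeat expansion of a motif to an exact bp length."""
    reps = -(-length // len(motif))
    return (motif * reps)[:length]


def write_calls_vcf(
    callset: CallSet, catalog: dict[str, StrLocus], path: str | Path
) -> None:
    """Write calls as VCF 4.2 with REF/ALT as repeat expansions.

    FORMAT carries GT (allele indices; one entry for hemizygous calls), DP
    (reads spanning the locus) and AD (reads supporting each called allele).
    Positions are 1-based; the bp-length semantics of each allele are
    recovered from the REF/ALT string lengths.
    """
    import pysam

    samples = callset.samples()
    chrom_len: dict[str, int] = {}
    for loc in catalog.values():
        chrom_len[loc.chrom] = max(chrom_len.get(loc.chrom, 0), loc.end + 1000)
    header = pysam.VariantHeader()
    header.add_line('##source=strland')
    header.add_line('##INFO=<ID=MOTIF,Number=1,Type=String,Description="Canonical repeat motif">')
    header.add_line('##INFO=<ID=PERIOD,Number=1,Type=Integer,Description="Motif length in bp">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Reads spanning the locus">')
    header.add_line('##FORMAT=<ID=AD,Number=.,Type=Integer,Description="Reads supporting each called allele">')
    for chrom in sorted(chrom_len):
        header.add_line(f"##contig=<ID={chrom},length={chrom_len[chrom]}>")
    for s in samples:
        header.add_sample(s)

    by_locus = callset.by_locus()
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for lid in sorted(by_locus, key=lambda x: (catalog[x].chrom, catalog[x].start)):
            locus = catalog[lid]
            calls = by_locus[lid]
            lengths = sorted({a for c in calls for a in c.alleles} | {locus.ref_len_bp})
            ref_seq = _expand(locus.motif, locus.ref_len_bp)
            alts = [_expand(locus.motif, L) for L in lengths if L != locus.ref_len_bp]
            allele_index = {locus.ref_len_bp: 0}
            for i, L in enumerate([L for L in lengths if L != locus.ref_len_bp], 1):
                allele_index[L] = i
            rec = vcf.new_record(
                contig=locus.chrom,
                start=locus.start,
                stop=locus.end,
                # "." marks a record with no alternative allele observed
                alleles=tuple([ref_seq] + alts) if alts else (ref_seq, "."),
                id=lid.replace(":", "_"),
            )
            rec.info["MOTIF"] = locus.motif
            rec.info["PERIOD"] = locus.period
            for c in calls:
                gt = tuple(allele_index[a] for a in c.alleles)
                rec.samples[c.sample]["GT"] = gt
                rec.samples[c.sample]["DP"] = c.coverage
                rec.samples[c.sample]["AD"] = list(c.supports)
            vcf.write(rec)


def read_calls_vcf(path: str | Path) -> tuple[CallSet, dict[str, StrLocus]]:
    """Read a VCF written by :func:`write_calls_vcf`.

    Returns the callset and a locus table reconstructed from the records
    (purity/score are not stored in the VCF and come back as 1.0/0).
    Records whose GT references an absent ALT raise with the record's
    position.
    """
    import pysam

    _validate_gt_indices(path)
    calls: list[StrCall] = []
    catalog: dict[str, StrLocus] = {}
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            motif = rec.info["MOTIF"]
            lid = f"{rec.chrom}:{rec.start}-{rec.stop}"
            catalog[lid] = StrLocus(
                chrom=rec.chrom,
                start=rec.start,
                end=rec.stop,
                motif=motif,
                score=0,
                purity=1.0,
            )
            allele_len = [len(a) for a in rec.alleles]
            for sample, data in rec.samples.items():
                gt = data.get("GT")
                if gt is None or all(g is None for g in gt):
                    continue
                try:
                    alleles = tuple(allele_len[g] for g in gt if g is not None)
                except IndexError as exc:
                    raise ValueError(
                        f"{path}: GT references absent ALT at {rec.chrom}:{rec.pos}"
                    ) from exc
                ad = data.get("AD")
                supports = tuple(int(x) for x in ad) if ad is not None else ()
                calls.append(
                    StrCall(
                        sample=sample,
                        locus=lid,
                        alleles=alleles,
                        coverage=int(data.get("DP") or 0),
                        supports=supports,
                    )
                )
    return CallSet(calls=calls), catalog


def _validate_gt_indices(path: str | Path) -> None:
    """Reject GT fields referencing an ALT allele the record does not carry.

    The htslib parser silently maps such indices to missing, so malformed
    records are caught with a textual pass that reports the line number.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 10:
                continue
            alt = parts[4]
            n_alleles = 1 + (0 if alt in (".", "") else len(alt.split(",")))
            fmt = parts[8].split(":")
            if "GT" not in fmt:
                continue
            gt_pos = fmt.index("GT")
            for sample_field in parts[9:]:
                gt = sample_field.split(":")[gt_pos]
                for token in gt.replace("|", "/").split("/"):
                    if token not in (".", "") and int(token) >= n_alleles:
                        raise ValueError(
                            f"{path}: line {lineno}: GT references absent ALT "
                            f"(index {token}, {n_alleles} alleles)"
                        )


# ---------------------------------------------------------------------------
# calibration JSON, FASTA, config


def write_calibration(cal: CalibrationResult, path: str | Path) -> None:
    payload = dataclasses.asdict(cal)
    payload["thresholds"] = {str(k): v for k, v in cal.thresholds.items()}
    payload["achieved_fp"] = {str(k): v for k, v in cal.achieved_fp.items()}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_calibration(path: str | Path) -> CalibrationResult:
    with open(path) as fh:
        payload = json.load(fh)
    payload["thresholds"] = {int(k): int(v) for k, v in payload["thresholds"].items()}
    payload["achieved_fp"] = {int(k): float(v) for k, v in payload["achieved_fp"].items()}
    return CalibrationResult(**payload)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load all sequences from a FASTA file."""
    from pyfaidx import Fasta

    with Fasta(str(path), as_raw=True, sequence_always_upper=True) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def load_config(path: str | Path) -> dict:
    """Structured key-value configuration (YAML, one section per subcommand)."""
    import yaml

    with open(path) as fh:
        return yaml.safe_load(fh) or {}
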