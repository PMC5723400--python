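"""Reading, validating, and summarizing multilocus genotype tables.

Supports the two table dialects common in seagrass population genetics:
GenAlEx-style wide tables (two adjacent columns per locus) and genepop
files (4- or 6-digit concatenated allele codes, ``POP``-delimited).
Genotypes are diploid; allele labels are opaque text compared by equality
only, so microsatellite fragment sizes and SNP bases pass through
unchanged. A genotype is missing as a whole if either allele carries the
missing code — partial diploid calls are not interpretable for clone
matching.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel used internally for a missing genotype call.
MISSING = None


class GenotypeFormatError(ValueError):
    """Malformed genotype table (column layout, allele encoding)."""


class GenotypeValidationError(ValueError):
    """Structurally valid file with invalid content (duplicates, empty)."""


Call = "tuple[str, str] | None"


def _normalize_call(a: str, b: str, missing_code: str) -> "tuple[str, str] | None":
    """Order-normalize one diploid call; missing if either allele is missing."""
    a, b = str(a).strip(), str(b).strip()
    if a == missing_code or b == missing_code or a == "" or b == "":
        return None
    return (a, b) if a <= b else (b, a)


@dataclass
class GenotypeMatrix:
    """Samples x loci diploid allele calls for one site and species.

    ``calls[i][j]`` is the order-normalized allele pair of sample *i* at
    locus *j*, or ``None`` when the genotype is missing.
    """

    site_id: str
    species: str
    sample_ids: list
    locus_ids: list
    calls: list  # list of rows; each row a list of (a, b) tuples or None

    def __post_init__(self):
        n, l = len(self.sample_ids), len(self.locus_ids)
        if len(set(self.sample_ids)) != n:
            raise GenotypeValidationError(
                f"duplicate sample ids at site {self.site_id!r}"
            )
        for i, row in enumerate(self.calls):
            if len(row) != l:
                raise GenotypeValidationError(
                    f"sample {self.sample_ids[i]!r} has {len(row)} calls, expected {l}"
                )
            for j, c in enumerate(row):
                if c is not None:
                    a, b = c
                    if a > b:
                        row[j] = (b, a)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def genotype(self, i: int, j: int):
        return self.calls[i][j]


@dataclass
class AlleleFrequencyTable:
    """Per-locus allele frequencies from non-missing genotypes.

    ``freqs[locus]`` maps allele label -> frequency; ``used[locus]`` is the
    count of non-missing genotypes behind those frequencies. Loci with no
    usable genotypes are absent entirely.
    """

    locus_ids: list
    freqs: dict = field(default_factory=dict)
    used: dict = field(default_factory=dict)

    def __post_init__(self):
        for locus in self.locus_ids:
            p = self.freqs[locus]
            total = sum(p.values())
            if abs(total - 1.0) > 1e-9:
                raise GenotypeValidationError(
                    f"allele frequencies at {locus!r} sum to {total}, not 1"
                )
            if any(v <= 0 for v in p.values()):
                raise GenotypeValidationError(f"non-positive frequency at {locus!r}")


def allele_frequencies(g: GenotypeMatrix) -> AlleleFrequencyTable:
    """Allele frequencies per locus, excluding missing genotypes.

    p_i = (count of allele i over non-missing genotypes) / (2 x non-missing
    genotype count). A locus that is missing in every sample is dropped with
    a warning rather than reported with an empty spectrum.
    """
    freqs, used, kept = {}, {}, []
    for j, locus in enumerate(g.locus_ids):
        counts: dict = {}
        n_used = 0
        for row in g.calls:
            c = row[j]
            if c is None:
                continue
            n_used += 1
            for allele in c:
                counts[allele] = counts.get(allele, 0) + 1
        if n_used == 0:
            logger.warning("locus %r entirely missing; dropped", locus)
            continue
        denom = 2 * n_used
        freqs[locus] = {a: k / denom for a, k in counts.items()}
        used[locus] = n_used
        kept.append(locus)
    return AlleleFrequencyTable(locus_ids=kept, freqs=freqs, used=used)


# ---------------------------------------------------------------------------
# GenAlEx-style wide dialect


def read_genalex_wide(
    path,
    missing_code: str = "0",
    delimiter: str = ",",
    species: str = "",
) -> GenotypeMatrix:
    """Read a GenAlEx-style wide table.

    Header row 1 carries locus names over paired allele columns; each data
    row is one sample; the first two columns are sample id and
    population/site. Locus names may appear once over the pair (second
    column blank or suffixed ``.2``/``_2``) or be repeated.
    """
    df = pd.read_csv(path, sep=delimiter, header=0, dtype=str, keep_default_na=False)
    if df.shape[0] == 0:
        raise GenotypeValidationError(f"{path}: empty genotype table")
    header = list(df.columns)
    if len(header) < 4:
        raise GenotypeFormatError(f"{path}: need sample, site and >=1 locus pair")
    allele_cols = header[2:]
    if len(allele_cols) % 2 != 0:
        # name the locus implied by the dangling column
        dangling = re.sub(r"([._]2|\.1)$", "", str(allele_cols[-1]))
        raise GenotypeFormatError(
            f"{path}: odd number of allele columns; locus {dangling!r} "
            "has a single allele column"
        )
    locus_ids = []
    for k in range(0, len(allele_cols), 2):
        name = str(allele_cols[k])
        name = re.sub(r"([._]1)$", "", name)
        locus_ids.append(name)
    sample_ids = [str(s) for s in df.iloc[:, 0]]
    site_vals = set(str(s) for s in df.iloc[:, 1])
    site_id = sorted(site_vals)[0] if site_vals else ""
    calls = []
    for _, row in df.iterrows():
        vals = [str(v) for v in row.iloc[2:]]
        calls.append(
            [
                _normalize_call(vals[2 * j], vals[2 * j + 1], missing_code)
                for j in range(len(locus_ids))
            ]
        )
    return GenotypeMatrix(
        site_id=site_id,
        species=species,
        sample_ids=sample_ids,
        locus_ids=locus_ids,
        calls=calls,
    )


def write_genalex_wide(g: GenotypeMatrix, path, missing_code: str = "0",
                       delimiter: str = ",") -> None:
    """Write the wide dialect that :func:`read_genalex_wide` reads back."""
    cols = ["sample_id", "site"]
    for locus in g.locus_ids:
        cols += [locus, f"{locus}.2"]
    rows = []
    for sid, row in zip(g.sample_ids, g.calls):
        rec = [sid, g.site_id]
        for c in row:
            rec += [missing_code, missing_code] if c is None else [c[0], c[1]]
        rows.append(rec)
    pd.DataFrame(rows, columns=cols).to_csv(path, sep=delimiter, index=False)


# ---------------------------------------------------------------------------
# genepop dialect


def read_genepop(path, species: str = "") -> "list[GenotypeMatrix]":
    """Read a genepop file into one GenotypeMatrix per POP block.

    Handles 4-digit (2 digits per allele) and 6-digit (3 digits per allele)
    encodings; an allele code of all zeros is missing, as is the whole-call
    code 0000/000000.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if len(lines) < 3:
        raise GenotypeValidationError(f"{path}: truncated genepop file")
    # line 1 is a free-text title
    locus_ids: list = []
    i = 1
    while i < len(lines) and lines[i].strip().upper() != "POP":
        # locus names: one per line, or comma-separated on one line
        for tok in lines[i].split(","):
            tok = tok.strip()
            if tok:
                locus_ids.append(tok)
        i += 1
    if not locus_ids:
        raise GenotypeValidationError(f"{path}: no locus names before first POP")
    matrices = []
    pop_idx = 0
    while i < len(lines):
        assert lines[i].strip().upper() == "POP"
        i += 1
        pop_idx += 1
        sample_ids, calls, site_id = [], [], f"pop{pop_idx}"
        while i < len(lines) and lines[i].strip().upper() != "POP":
            line = lines[i].strip()
            i += 1
            if not line:
                continue
            if "," not in line:
                raise GenotypeFormatError(f"{path}: genepop row lacks comma: {line!r}")
            name, geno = line.split(",", 1)
            name = name.strip()
            toks = geno.split()
            if len(toks) != len(locus_ids):
                raise GenotypeFormatError(
                    f"{path}: sample {name!r} has {len(toks)} loci, "
                    f"expected {len(locus_ids)}"
                )
            row = []
            for tok in toks:
                if len(tok) not in (4, 6) or not tok.isdigit():
                    raise GenotypeFormatError(
                        f"{path}: bad allele code {tok!r} for sample {name!r}"
                    )
                half = len(tok) // 2
                a, b = tok[:half], tok[half:]
                zero = "0" * half
                row.append(None if a == zero or b == zero
                           else ((a, b) if a <= b else (b, a)))
            sample_ids.append(name)
            calls.append(row)
            site_id = name.rsplit("_", 1)[0] if "_" in name else site_id
        if not sample_ids:
            raise GenotypeValidationError(f"{path}: empty POP block {pop_idx}")
        matrices.append(
            GenotypeMatrix(site_id=site_id, species=species,
                           sample_ids=sample_ids, locus_ids=list(locus_ids),
                           calls=calls)
        )
    if not matrices:
        raise GenotypeValidationError(f"{path}: no POP blocks")
    return matrices


def read_genotype_table(path, dialect: str, missing_code: str = "0",
                        species: str = "", delimiter: str = ",") -> GenotypeMatrix:
    """Read one site's genotype table in the declared dialect.

    For genepop files with several POP blocks only the first is returned;
    use :func:`read_genepop` directly for multi-population files.
    """
    if dialect == "genalex_wide":
        return read_genalex_wide(path, missing_code=missing_code,
                                 delimiter=delimiter, species=species)
    if dialect == "genepop":
        return read_genepop(path, species=species)[0]
    raise ValueError(f"unknown dialect {dialect!r}")


def summarize(g: GenotypeMatrix) -> pd.DataFrame:
    """Per-locus summary: alleles observed, missing calls, genotypes used."""
    rows = []
    for j, locus in enumerate(g.locus_ids):
        alleles = set()
        n_missing = 0
        for row in g.calls:
            c = row[j]
            if c is None:
                n_missing += 1
            else:
                alleles.update(c)
        rows.append({"locus": locus, "n_alleles": len(alleles),
                     "n_missing": n_missing, "n_used": g.n_samples - n_missing})
    return pd.DataFrame(rows)
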