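"""Domain types and readers/writers for the reduced SNP panel workflow.

Every downstream stage consumes the containers defined here; no other module
re-parses raw text. Genotypes are unordered allele pairs canonicalised to
lexicographic order at parse time ("A/G", never "G/A"); missing calls are the
sentinel string ``NoCall``. The gonosomal sex marker uses the calls ``X``
(no Y allele observed) and ``XY``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

NO_CALL = "NoCall"
SEX_MARKER_ID = "AmelY1"

SUBSET_FLAGS = frozenset(
    {
        "individualisation",
        "parentage_diversity",
        "line_discrimination",
        "sex",
        "cross_species",
        "posthitis_meta",
    }
)

#: controlled vocabularies for pedigree / label columns
SEXES = ("M", "F", "U")
LINES = ("LL", "LC", "U")


class PanelError(ValueError):
    """Hard error for malformed inputs (unknown markers, bad alleles, cycles)."""


@dataclass(frozen=True)
class MarkerDef:
    """One panel marker: id, chromosome, the two alleles and subset flags."""

    marker_id: str
    chromosome: str
    allele_a: str
    allele_b: str
    subsets: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if self.allele_a == self.allele_b:
            raise PanelError(f"{self.marker_id}: allele_a == allele_b ({self.allele_a})")
        unknown = set(self.subsets) - SUBSET_FLAGS
        if unknown:
            raise PanelError(f"{self.marker_id}: unknown subset flags {sorted(unknown)}")
        if "sex" in self.subsets and self.is_autosomal:
            raise PanelError(f"{self.marker_id}: sex markers must be non-autosomal")

    @property
    def is_autosomal(self) -> bool:
        return self.chromosome not in ("X", "Y", "XY-homolog")

    @property
    def alleles(self) -> tuple:
        return (self.allele_a, self.allele_b)

    def genotype(self, a1: str, a2: str) -> str:
        """Canonical unordered genotype string from two allele symbols."""
        if a1 not in self.alleles or a2 not in self.alleles:
            raise PanelError(
                f"{self.marker_id}: allele(s) {a1},{a2} not in defined alleles {self.alleles}"
            )
        return "/".join(sorted((a1, a2)))

    def dosage(self, call: str):
        """Count of allele_b in a genotype string; None for NoCall."""
        if call == NO_CALL:
            return None
        return call.count(self.allele_b)

    @property
    def genotypes(self) -> tuple:
        """The three canonical genotype strings (hom-a, het, hom-b)."""
        a, b = sorted(self.alleles)
        return (f"{a}/{a}", f"{a}/{b}", f"{b}/{b}")


def default_panel(seed_alleles: int = 0) -> list:
    """The shipped 96-marker default panel layout.

    90 polymorphic autosomal markers for individualisation, of which 63 form
    the parentage/diversity subset and 18 the breeding-line subset; 5
    autosomal markers monomorphic in the focal species for cross-species
    detection; and one Y-associated marker for sex determination. A few loci
    additionally carry the posthitis metadata flag.
    """
    allele_pairs = [("A", "C"), ("A", "G"), ("A", "T"), ("C", "G"), ("C", "T"), ("G", "T")]
    markers = []
    for i in range(95):
        mid = f"BB{i + 1:04d}"
        flags = {"individualisation"} if i < 90 else {"cross_species"}
        if i < 63:
            flags.add("parentage_diversity")
        if 63 <= i < 81:
            flags.add("line_discrimination")
        if i in (82, 85, 88, 91):
            flags.add("posthitis_meta")
        a, b = allele_pairs[(i + seed_alleles) % len(allele_pairs)]
        markers.append(
            MarkerDef(mid, str(i % 29 + 1), a, b, frozenset(flags))
        )
    markers.append(MarkerDef(SEX_MARKER_ID, "XY-homolog", "X", "Y", frozenset({"sex"})))
    return markers


def subset(markers: list, flag: str) -> list:
    """Markers carrying a given subset flag, panel order preserved."""
    if flag not in SUBSET_FLAGS:
        raise PanelError(f"unknown subset flag {flag!r}")
    return [m for m in markers if flag in m.subsets]


@dataclass
class ReplicateCalls:
    """Replicate x marker call table for one sample."""

    sample_id: str
    calls: pd.DataFrame  # index: replicate ids, columns: marker ids
    individual_id: str | None = None
    sample_type: str = "noninvasive"

    @property
    def r(self) -> int:
        return len(self.calls)

    @property
    def markers(self) -> list:
        return list(self.calls.columns)


@dataclass
class GenotypeMatrix:
    """Consensus diploid genotypes: one row per individual, one column per marker.

    ``labels`` holds the controlled-vocabulary annotations (group/ESU, breeding
    line, sex); ``provenance`` optionally carries consensus metadata such as
    replicate counts and per-sample call rates.
    """

    genotypes: pd.DataFrame  # individuals x markers, genotype strings / NoCall
    labels: pd.DataFrame | None = None  # index: individuals; columns incl. group,line,sex
    provenance: pd.DataFrame | None = None

    def __post_init__(self):
        if self.genotypes.index.has_duplicates:
            raise PanelError("GenotypeMatrix requires one row per individual")
        if self.labels is None:
            self.labels = pd.DataFrame(
                {"group": "focal", "line": "U", "sex": "U"}, index=self.genotypes.index
            )
        self.labels = self.labels.reindex(self.genotypes.index)

    @property
    def individuals(self) -> list:
        return list(self.genotypes.index)

    def called_mask(self) -> pd.DataFrame:
        return self.genotypes != NO_CALL

    def call_rate(self) -> pd.Series:
        """Per-individual fraction of non-missing calls over the matrix columns."""
        return self.called_mask().mean(axis=1)

    def dosage(self, markers: list) -> pd.DataFrame:
        """Individuals x markers matrix counting allele_b copies; NaN = NoCall."""
        cols = {}
        for m in markers:
            if m.marker_id not in self.genotypes.columns:
                continue
            col = self.genotypes[m.marker_id]
            cols[m.marker_id] = col.map(
                lambda g, b=m.allele_b: float(g.count(b)) if g != NO_CALL else float("nan")
            )
        return pd.DataFrame(cols, index=self.genotypes.index)

    def restrict(self, markers: list) -> "GenotypeMatrix":
        ids = [m.marker_id for m in markers if m.marker_id in self.genotypes.columns]
        return GenotypeMatrix(self.genotypes[ids].copy(), self.labels.copy(), self.provenance)


@dataclass
class Pedigree:
    """Acyclic sire/dam pedigree with sex, breeding line and alive flags."""

    table: pd.DataFrame  # columns: id, sire, dam, sex, line, alive; index = id

    def __post_init__(self):
        self._validate()

    def _validate(self):
        t = self.table
        g = self.to_networkx()
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            cycle = None
        if cycle:
            path = " -> ".join(str(u) for u, _ in cycle) + f" -> {cycle[-1][1]}"
            raise PanelError(f"pedigree contains a cycle: {path}")
        sex = t["sex"]
        for col, want, word in (("sire", "F", "sire"), ("dam", "M", "dam")):
            parents = t[col].dropna()
            bad = [p for p in parents if p in sex.index and sex.loc[p] == want]
            if bad:
                raise PanelError(f"{word}(s) recorded with sex {want}: {sorted(set(bad))}")

    def to_networkx(self) -> nx.DiGraph:
        """Parent -> offspring directed graph."""
        g = nx.DiGraph()
        g.add_nodes_from(self.table.index)
        for iid, row in self.table.iterrows():
            for p in (row["sire"], row["dam"]):
                if pd.notna(p):
                    g.add_edge(p, iid)
        return g

    @property
    def founders(self) -> list:
        t = self.table
        return list(t.index[t["sire"].isna() & t["dam"].isna()])

    def topological_order(self) -> list:
        """Individuals ordered parents-before-offspring (deterministic)."""
        return list(nx.lexicographical_topological_sort(self.to_networkx()))

    def parents(self, iid: str) -> tuple:
        row = self.table.loc[iid]
        s = row["sire"] if pd.notna(row["sire"]) else None
        d = row["dam"] if pd.notna(row["dam"]) else None
        return s, d

    def po_pairs(self) -> set:
        """All (parent, offspring) pairs as an unordered-pair set of frozensets."""
        out = set()
        for iid in self.table.index:
            for p in self.parents(iid):
                if p is not None:
                    out.add(frozenset((p, iid)))
        return out


# ---------------------------------------------------------------------------
# call tables


def _parse_call(raw, marker: MarkerDef, context: str) -> str:
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return NO_CALL
    s = str(raw).strip()
    if s == "" or s.lower() in ("nocall", "no call", "na", "-", "./."):
        return NO_CALL
    if not marker.is_autosomal:
        u = s.upper().replace(":", "").replace("/", "")
        if u in ("X", "XX"):
            return "X"
        if u in ("XY", "YX", "Y"):
            return "XY"
        raise PanelError(f"{context}: bad sex-marker call {raw!r}")
    for sep in (":", "/"):
        if sep in s:
            parts = s.split(sep)
            if len(parts) != 2:
                raise PanelError(f"{context}: malformed call {raw!r}")
            return marker.genotype(parts[0].strip(), parts[1].strip())
    if len(s) == 1:
        return marker.genotype(s, s)
    if len(s) == 2:
        return marker.genotype(s[0], s[1])
    raise PanelError(f"{context}: malformed call {raw!r}")


def read_call_table(path, marker_defs: list) -> list:
    """Read a delimited replicate-level call table (long or wide dialect).

    Long format has columns ``sample_id, replicate_id, marker_id, call``
    (optionally ``individual_id, sample_type``); wide format has one column
    per marker. Unknown marker ids and alleles outside a marker's definition
    are hard errors naming the offenders.
    """
    by_id = {m.marker_id: m for m in marker_defs}
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    if df.empty:
        raise PanelError(f"{path}: no records")
    cols = list(df.columns)
    meta_cols = {"sample_id", "replicate_id", "individual_id", "sample_type"}
    if "marker_id" in cols and "call" in cols:
        long = df
    else:
        marker_cols = [c for c in cols if c not in meta_cols]
        unknown = [c for c in marker_cols if c not in by_id]
        if unknown:
            raise PanelError(f"{path}: unknown marker id(s) in header: {unknown}")
        long = df.melt(
            id_vars=[c for c in cols if c in meta_cols],
            value_vars=marker_cols,
            var_name="marker_id",
            value_name="call",
        )
    for req in ("sample_id", "replicate_id"):
        if req not in long.columns:
            raise PanelError(f"{path}: missing required column {req!r}")
    unknown = sorted(set(long["marker_id"]) - set(by_id))
    if unknown:
        raise PanelError(f"{path}: unknown marker id(s): {unknown}")

    out = []
    for sid, grp in long.groupby("sample_id", sort=True):
        parsed = grp.copy()
        parsed["call"] = [
            _parse_call(raw, by_id[mid], f"sample {sid}, marker {mid}")
            for raw, mid in zip(grp["call"], grp["marker_id"])
        ]
        wide = parsed.pivot_table(
            index="replicate_id", columns="marker_id", values="call", aggfunc="first"
        ).fillna(NO_CALL)
        wide = wide.reindex(columns=[m for m in by_id if m in wide.columns])
        ind = grp["individual_id"].dropna().iloc[0] if "individual_id" in grp and grp["individual_id"].notna().any() else None
        styp = grp["sample_type"].dropna().iloc[0] if "sample_type" in grp and grp["sample_type"].notna().any() else "noninvasive"
        out.append(ReplicateCalls(str(sid), wide, ind, str(styp)))
    return out


def write_call_table(rcs: list, path) -> None:
    """Write replicate calls in the long dialect (the writer's only dialect)."""
    rows = []
    for rc in rcs:
        for rep_id, row in rc.calls.iterrows():
            for mid, call in row.items():
                rows.append(
                    {
                        "sample_id": rc.sample_id,
                        "replicate_id": rep_id,
                        "individual_id": rc.individual_id,
                        "sample_type": rc.sample_type,
                        "marker_id": mid,
                        "call": call,
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# pedigrees


def read_pedigree(path) -> Pedigree:
    """Read a studbook-style pedigree CSV (id, sire, dam, sex, line, alive).

    Missing parents may be empty or "0". Parents referenced but not listed are
    auto-created as unknown-sex founders with a warning.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    if df.empty:
        raise PanelError(f"{path}: no records")
    df.columns = [c.strip().lower() for c in df.columns]
    for req in ("id", "sire", "dam"):
        if req not in df.columns:
            raise PanelError(f"{path}: missing required column {req!r}")

    def norm_parent(v):
        if pd.isna(v) or str(v).strip() in ("", "0"):
            return None
        return str(v).strip()

    records = {}
    for _, row in df.iterrows():
        iid = str(row["id"]).strip()
        sex = str(row.get("sex", "U") or "U").strip().upper()[:1] or "U"
        line = str(row.get("line", "U") or "U").strip().upper()
        if sex not in SEXES:
            sex = "U"
        if line not in LINES:
            line = "U"
        alive = str(row.get("alive", "true")).strip().lower() in ("1", "true", "yes", "y")
        records[iid] = {
            "sire": norm_parent(row["sire"]),
            "dam": norm_parent(row["dam"]),
            "sex": sex,
            "line": line,
            "alive": alive,
        }
    # auto-create referenced-but-absent parents as founders
    for iid, rec in list(records.items()):
        for p in (rec["sire"], rec["dam"]):
            if p is not None and p not in records:
                warnings.warn(f"pedigree: parent {p!r} not listed; created as unknown-sex founder")
                records[p] = {"sire": None, "dam": None, "sex": "U", "line": "U", "alive": False}
    table = pd.DataFrame.from_dict(records, orient="index")
    table.index.name = "id"
    return Pedigree(table)


def write_pedigree(ped: Pedigree, path) -> None:
    out = ped.table.reset_index()
    out["sire"] = out["sire"].fillna("0")
    out["dam"] = out["dam"].fillna("0")
    out.to_csv(path, index=False)


def pedigree_from_records(records: list) -> Pedigree:
    """Build a Pedigree from dicts with keys id, sire, dam, sex, line, alive."""
    table = pd.DataFrame(records).set_index("id")
    for col, default in (("sire", None), ("dam", None), ("sex", "U"), ("line", "U"), ("alive", True)):
        if col not in table.columns:
            table[col] = default
        elif col in ("sex", "line", "alive"):
            table[col] = table[col].where(table[col].notna(), default)
    table["alive"] = table["alive"].astype(bool)
    return Pedigree(table[["sire", "dam", "sex", "line", "alive"]])


# ---------------------------------------------------------------------------
# genotype matrices


def write_genotype_matrix(gm: GenotypeMatrix, path, format: str = "native-csv",
                          markers: list | None = None) -> None:
    """Write consensus genotypes as native CSV, PLINK PED(+MAP) or VCF v4.2.

    Native CSV round-trips losslessly through :func:`read_genotype_matrix`.
    PED encodes NoCall as ``0 0``; VCF as ``./.``. The PLINK/VCF exports need
    ``markers`` for allele definitions; placeholder positions are used when no
    chromosome coordinates exist.
    """
    if gm.genotypes.empty:
        raise PanelError("cannot write an empty GenotypeMatrix")
    if format == "native-csv":
        out = pd.concat([gm.labels, gm.genotypes], axis=1)
        out.index.name = "individual_id"
        out.to_csv(path)
        return
    if markers is None:
        raise PanelError(f"{format} export requires marker definitions")
    by_id = {m.marker_id: m for m in markers}
    mids = [c for c in gm.genotypes.columns if c in by_id]
    if format == "plink-ped":
        ped_lines = []
        for iid, row in gm.genotypes.iterrows():
            sex_code = {"M": "1", "F": "2"}.get(gm.labels.loc[iid, "sex"], "0")
            fields = ["FAM", str(iid), "0", "0", sex_code, "-9"]
            for mid in mids:
                g = row[mid]
                fields.extend(["0", "0"] if g == NO_CALL else g.split("/"))
            ped_lines.append(" ".join(fields))
        with open(path, "w") as fh:
            fh.write("\n".join(ped_lines) + "\n")
        map_path = str(path).rsplit(".", 1)[0] + ".map"
        with open(map_path, "w") as fh:
            for i, mid in enumerate(mids):
                chrom = by_id[mid].chromosome
                chrom = chrom if chrom.isdigit() else "0"
                fh.write(f"{chrom} {mid} 0 {i + 1}\n")
        return
    if format == "vcf":
        lines = [
            "##fileformat=VCFv4.2",
            "##source=wisentpanel",
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        ]
        chroms = []
        for mid in mids:
            c = by_id[mid].chromosome
            if c not in chroms:
                chroms.append(c)
        lines += [f"##contig=<ID={c}>" for c in chroms]
        lines.append(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(i) for i in gm.genotypes.index)
        )
        for i, mid in enumerate(mids):
            m = by_id[mid]
            gts = []
            for iid in gm.genotypes.index:
                g = gm.genotypes.loc[iid, mid]
                if g == NO_CALL:
                    gts.append("./.")
                else:
                    d = m.dosage(g)
                    gts.append({0: "0/0", 1: "0/1", 2: "1/1"}[d])
            lines.append(
                f"{m.chromosome}\t{i + 1}\t{mid}\t{m.allele_a}\t{m.allele_b}\t.\t.\t.\tGT\t"
                + "\t".join(gts)
            )
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
        return
    raise PanelError(f"unknown genotype-matrix format {format!r}")


def read_genotype_matrix(path, marker_defs: list | None = None) -> GenotypeMatrix:
    """Read the native-CSV genotype matrix written by :func:`write_genotype_matrix`."""
    df = pd.read_csv(path, index_col="individual_id", dtype=str)
    if df.empty:
        raise PanelError(f"{path}: no records")
    label_cols = [c for c in ("group", "line", "sex") if c in df.columns]
    labels = df[label_cols]
    genos = df.drop(columns=label_cols).fillna(NO_CALL)
    if marker_defs is not None:
        by_id = {m.marker_id: m for m in marker_defs}
        unknown = [c for c in genos.columns if c not in by_id]
        if unknown:
            raise PanelError(f"{path}: unknown marker id(s): {unknown}")
    genos.index = genos.index.astype(str)
    genos.index.name = None
    labels.index = genos.index
    return GenotypeMatrix(genos, labels)
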