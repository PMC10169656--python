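"""Readers and writers for the external formats the pipeline touches.

Formats: TSV intensity matrices (features x samples, log2 scale), SIF-like
signed causal networks, GMT gene-set collections, regulon and
regulatory-site tables, and the mechanistic-model export bundle
(node/edge TSVs + SIF + GraphML + paths JSON).

Every reader validates strictly and raises :class:`FormatError` naming the
offending row; writers emit byte-deterministic output (lexicographic order).
Missing intensities are kept as explicit missing values (NaN), never zero:
a zero would silently corrupt log-space statistics.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd

from .network import MechanisticModel, PriorNetwork, SignedPath

logger = logging.getLogger(__name__)

MATRIX_KINDS = ("proteome", "phospho")
LOC_PROB_COLUMN = "loc_prob"
CLASS_I_THRESHOLD = 0.75


class FormatError(ValueError):
    """Malformed external input."""


_SITE_RE = re.compile(r"^(?P<protein>.+)_(?P<residue>[STY])(?P<position>[1-9][0-9]*)$")


@dataclass(frozen=True, order=True)
class PhosphositeID:
    """A phosphosite: host protein, residue (S/T/Y) and 1-based position.

    Canonical string form is ``PROTEIN_R###``, e.g. ``CDK7_T170``.
    """

    protein: str
    residue: str
    position: int

    def __post_init__(self) -> None:
        if self.residue not in ("S", "T", "Y"):
            raise ValueError(f"residue must be S, T or Y, got {self.residue!r}")
        if not isinstance(self.position, int) or self.position < 1:
            raise ValueError(f"position must be an integer >= 1, got {self.position!r}")
        if not self.protein:
            raise ValueError("protein symbol must be non-empty")

    @classmethod
    def parse(cls, text: str) -> "PhosphositeID":
        m = _SITE_RE.match(str(text))
        if m is None:
            raise FormatError(f"unparseable phosphosite identifier: {text!r}")
        return cls(m["protein"], m["residue"], int(m["position"]))

    def __str__(self) -> str:
        return f"{self.protein}_{self.residue}{self.position}"


_SAMPLE_RE = re.compile(r"^(?P<genotype>.+)\.(?P<treatment>control|treated)\.r(?P<replicate>[1-9][0-9]*)$")

TREATMENTS = ("control", "treated")


@dataclass(frozen=True, order=True)
class SampleAnnotation:
    """Experimental annotation of one sample column.

    ``sample_id`` follows the convention ``<genotype>.<treatment>.r<replicate>``
    (e.g. ``ITD-JMD.treated.r1``); (genotype, treatment, replicate) must be
    unique within a matrix.
    """

    sample_id: str
    genotype: str
    treatment: str
    replicate: int

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise ValueError(f"treatment must be one of {TREATMENTS}, got {self.treatment!r}")
        if self.replicate < 1:
            raise ValueError("replicate index must be >= 1")

    @classmethod
    def parse(cls, sample_id: str) -> "SampleAnnotation":
        m = _SAMPLE_RE.match(str(sample_id))
        if m is None:
            raise FormatError(
                f"unparseable sample id {sample_id!r}; expected '<genotype>.<treatment>.r<n>'"
            )
        return cls(str(sample_id), m["genotype"], m["treatment"], int(m["replicate"]))

    @property
    def condition(self) -> str:
        """Condition label '<genotype>.<treatment>' used in contrasts."""
        return f"{self.genotype}.{self.treatment}"


class OmicsMatrix:
    """Log2 feature x sample intensity matrix with sample annotations.

    ``kind`` is ``"proteome"`` (rows = protein symbols) or ``"phospho"``
    (rows = canonical phosphosite strings, optionally with a localization
    probability per site).  Missing values are NaN.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        kind: str,
        loc_prob: pd.Series | None = None,
    ) -> None:
        if kind not in MATRIX_KINDS:
            raise ValueError(f"kind must be one of {MATRIX_KINDS}, got {kind!r}")
        dup = values.index[values.index.duplicated()].unique().tolist()
        if dup:
            raise FormatError(f"duplicate feature identifiers: {dup}")
        self.values = values.astype(float)
        self.kind = kind
        if len(set(values.columns)) != len(values.columns):
            raise FormatError("duplicate sample columns")
        self.samples = {c: SampleAnnotation.parse(c) for c in values.columns}
        keys = [(a.genotype, a.treatment, a.replicate) for a in self.samples.values()]
        if len(set(keys)) != len(keys):
            raise FormatError("duplicate (genotype, treatment, replicate) sample annotation")
        if loc_prob is not None:
            loc_prob = loc_prob.reindex(values.index).astype(float)
            bad = loc_prob[(loc_prob < 0) | (loc_prob > 1)].index.tolist()
            if bad:
                raise FormatError(f"localization probability outside [0,1] for: {bad}")
        self.loc_prob = loc_prob
        if kind == "phospho":
            for f in values.index:
                PhosphositeID.parse(f)  # raises FormatError naming the row

    # -- conveniences ------------------------------------------------------
    @property
    def features(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_features(self) -> int:
        return len(self.values.index)

    @property
    def genotypes(self) -> list[str]:
        return sorted({a.genotype for a in self.samples.values()})

    @property
    def conditions(self) -> list[str]:
        return sorted({a.condition for a in self.samples.values()})

    def columns_for(self, condition: str) -> list[str]:
        """Sample columns for a '<genotype>.<treatment>' condition label."""
        cols = [c for c, a in self.samples.items() if a.condition == condition]
        return cols

    def class_i(self, threshold: float = CLASS_I_THRESHOLD) -> "OmicsMatrix":
        """Restrict a phospho matrix to confidently localized (class I) sites.

        Sites with localization probability >= ``threshold`` are kept; a
        matrix without localization probabilities is returned unchanged.
        """
        if self.kind != "phospho" or self.loc_prob is None:
            return self
        keep = self.loc_prob[self.loc_prob >= threshold].index
        return OmicsMatrix(self.values.loc[keep], "phospho", self.loc_prob.loc[keep])

    def subset(self, features) -> "OmicsMatrix":
        feats = [f for f in features if f in self.values.index]
        lp = self.loc_prob.loc[feats] if self.loc_prob is not None else None
        return OmicsMatrix(self.values.loc[feats], self.kind, lp)


# ---------------------------------------------------------------------------
# matrices


def read_matrix(path: str | Path, kind: str) -> OmicsMatrix:
    """Read a TSV intensity matrix (first column = feature IDs, header = samples).

    Phospho matrices may carry a trailing ``loc_prob`` column with per-site
    localization probabilities in [0, 1].
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    loc_prob = None
    if LOC_PROB_COLUMN in df.columns:
        loc_prob = pd.to_numeric(df.pop(LOC_PROB_COLUMN), errors="raise")
    dup = df.index[df.index.duplicated()].unique().tolist()
    if dup:
        raise FormatError(f"{path}: duplicate feature identifiers: {dup}")
    try:
        values = df.apply(pd.to_numeric, errors="raise")
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: non-numeric intensity value ({exc})") from exc
    try:
        return OmicsMatrix(values, kind, loc_prob)
    except FormatError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_matrix(matrix: OmicsMatrix, path: str | Path) -> None:
    """Write a matrix as TSV, features sorted lexicographically (deterministic)."""
    out = matrix.values.sort_index()
    if matrix.loc_prob is not None:
        out = out.assign(**{LOC_PROB_COLUMN: matrix.loc_prob.sort_index()})
    out.to_csv(path, sep="\t", index_label="feature", lineterminator="\n")


# ---------------------------------------------------------------------------
# signed networks

_SIGN_WORDS_POS = {"1", "+1", "+", "activates", "activate", "activation", "stimulates"}
_SIGN_WORDS_NEG = {"-1", "−1", "-", "inhibits", "inhibit", "inhibition", "represses"}


def parse_sign(text) -> int:
    """Map a sign token to +1/-1.

    Accepts numeric signs and SIGNOR-style verbs (``up-regulates ...`` -> +1,
    ``down-regulates ...`` -> -1) so real database exports load unmodified.
    """
    s = str(text).strip().lower()
    if s in _SIGN_WORDS_POS or s.startswith("up-regulates"):
        return 1
    if s in _SIGN_WORDS_NEG or s.startswith("down-regulates"):
        return -1
    raise FormatError(f"unrecognized interaction sign: {text!r}")


def sign_word(sign: int) -> str:
    return "activates" if int(sign) > 0 else "inhibits"


def read_prior_network(
    path: str | Path,
    phenotypes: tuple[str, ...] = (),
    node_classes: dict | None = None,
) -> PriorNetwork:
    """Read a signed causal network from a headered TSV or a plain SIF file.

    TSV columns: ``source``, ``target``, ``sign`` and optional ``mechanism``;
    SIF rows: ``source<TAB>relation<TAB>target``.  Identical duplicated rows
    collapse to one edge; conflicting signs for the same pair are kept as two
    edges.  Nodes named in ``phenotypes`` (or auto-detected zero-out-degree
    nodes passed by the caller) are flagged as phenotype sinks.
    """
    path = Path(path)
    net = PriorNetwork()
    text = path.read_text().splitlines()
    rows: list[tuple[str, str, int, str, int]] = []
    if not text or all(not line.strip() for line in text):
        logger.warning("%s: empty network file", path)
        return net
    header = text[0].rstrip("\n").split("\t")
    if "source" in header and "target" in header:
        idx = {name: header.index(name) for name in header}
        if "sign" not in idx:
            raise FormatError(f"{path}: TSV network needs a 'sign' column")
        for lineno, line in enumerate(text[1:], start=2):
            if not line.strip():
                continue
            parts = line.split("\t")
            try:
                sign = parse_sign(parts[idx["sign"]])
            except (FormatError, IndexError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            mech = parts[idx["mechanism"]] if "mechanism" in idx and len(parts) > idx["mechanism"] else ""
            rows.append((parts[idx["source"]], parts[idx["target"]], sign, mech, lineno))
    else:
        for lineno, line in enumerate(text, start=1):
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(f"{path}:{lineno}: SIF rows need exactly 3 fields")
            try:
                sign = parse_sign(parts[1])
            except FormatError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            rows.append((parts[0], parts[2], sign, "", lineno))
    pheno = set(phenotypes)
    for source, target, sign, mech, lineno in rows:
        if target in pheno and target not in net.graph:
            net.add_node(target, phenotype=True)
        try:
            net.add_edge(source, target, sign, mech)
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
    for p in pheno:
        if p in net.graph:
            net.graph.nodes[p]["phenotype"] = True
            net.phenotypes.add(p)
    if node_classes:
        for node, klass in node_classes.items():
            if node in net.graph:
                net.graph.nodes[node]["node_class"] = klass
    return net


def write_network_tsv(network: PriorNetwork, path: str | Path) -> None:
    rows = [
        {"source": u, "target": v, "sign": s, "mechanism": m}
        for u, v, s, m in network.edge_list()
    ]
    pd.DataFrame(rows, columns=["source", "target", "sign", "mechanism"]).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


def write_sif(edges, path: str | Path) -> None:
    """Write (source, target, sign[, ...]) tuples as a SIF file."""
    lines = sorted(f"{u}\t{sign_word(s)}\t{v}" for u, v, s, *_ in edges)
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# gene sets (GMT)


class GeneSetCollection:
    """Named gene sets with descriptions (GMT semantics)."""

    def __init__(self, sets: dict[str, set[str]], descriptions: dict[str, str] | None = None):
        self.sets = {str(k): {str(m) for m in v} for k, v in sets.items()}
        self.descriptions = dict(descriptions or {})

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]

    def items(self):
        return sorted(self.sets.items())


def read_gmt(path: str | Path) -> GeneSetCollection:
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}:{lineno}: GMT rows need >= 3 tab-separated fields")
        name, desc, *members = parts
        sets[name] = {m for m in members if m}
        descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = [
        "\t".join([name, collection.descriptions.get(name, "na"), *sorted(members)])
        for name, members in collection.items()
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# regulons & regulatory sites (tabular)


def read_regulons(path: str | Path):
    from .activity import RegulonSet

    df = pd.read_csv(path, sep="\t", dtype={"regulator": str, "target": str})
    required = {"regulator", "class", "target", "sign"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: regulon table needs columns {sorted(required)}")
    return RegulonSet.from_frame(df)


def read_reg_sites(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"site": str, "protein": str})
    required = {"site", "protein", "effect"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: regulatory-site table needs columns {sorted(required)}")
    bad = df.loc[~df["effect"].isin([1, -1, "1", "-1", "+1"]), "site"].tolist()
    if bad:
        raise FormatError(f"{path}: regulatory-site effect must be +1/-1 for: {bad}")
    df["effect"] = df["effect"].astype(int)
    return df.sort_values(["protein", "site"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# mechanistic model bundle


def write_model(model: MechanisticModel, out_dir: str | Path) -> dict[str, Path]:
    """Write a model as node/edge TSVs, SIF, GraphML and a paths JSON.

    All files are byte-deterministic: nodes and edges are emitted in
    lexicographic order.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "nodes": out / "nodes.tsv",
        "edges": out / "edges.tsv",
        "sif": out / "model.sif",
        "graphml": out / "model.graphml",
        "paths": out / "paths.json",
        "meta": out / "model.json",
    }
    model.node_table().to_csv(paths["nodes"], sep="\t", index=False, lineterminator="\n")
    model.edge_table().to_csv(paths["edges"], sep="\t", index=False, lineterminator="\n")
    write_sif(sorted(model.edge_set()), paths["sif"])
    g = nx.MultiDiGraph()
    for n, d in sorted(model.graph.nodes(data=True)):
        g.add_node(
            n,
            sign=int(d.get("sign", 0)),
            score=float(d.get("score", float("nan"))),
            node_class=str(d.get("node_class", "other")),
        )
    for u, v, s in sorted(model.edge_set()):
        g.add_edge(u, v, key=s, sign=int(s))
    nx.write_graphml(g, paths["graphml"], named_key_ids=True)
    paths["paths"].write_text(model.paths_json() + "\n")
    paths["meta"].write_text(
        json.dumps(
            {"phenotype": model.phenotype, "direction": model.direction,
             "n_nodes": model.n_nodes, "n_edges": model.n_edges},
            indent=2, sort_keys=True,
        )
        + "\n"
    )
    return paths


def read_model(model_dir: str | Path) -> MechanisticModel:
    """Reconstruct a model from a :func:`write_model` bundle (content identity)."""
    d = Path(model_dir)
    meta = json.loads((d / "model.json").read_text())
    nodes = pd.read_csv(d / "nodes.tsv", sep="\t", dtype={"node": str})
    edges = pd.read_csv(d / "edges.tsv", sep="\t", dtype={"source": str, "target": str})
    raw_paths = json.loads((d / "paths.json").read_text())
    g = nx.MultiDiGraph()
    for _, row in nodes.iterrows():
        g.add_node(row["node"], sign=int(row["sign"]), score=float(row["score"]),
                   node_class=str(row["node_class"]))
    for _, row in edges.iterrows():
        s = int(row["sign"])
        g.add_edge(row["source"], row["target"], key=s, sign=s)
    paths = tuple(
        sorted(SignedPath(tuple(p["nodes"]), tuple(int(s) for s in p["edge_signs"]))
               for p in raw_paths)
    )
    return MechanisticModel(graph=g, phenotype=meta["phenotype"],
                            direction=int(meta["direction"]), paths=paths)
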