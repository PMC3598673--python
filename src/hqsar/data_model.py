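"""Domain types and table IO for descriptor-based uptake modelling.

The central objects are a :class:`DescriptorMatrix` (compounds x named,
class-labelled molecular descriptors) and per-polymorph :class:`ResponseSet`
objects holding Mitoxantrone uptake rates measured in the presence of each
competing substrate, both as raw rates and as percent of the
Mitoxantrone-alone control.

Descriptor tables travel as delimited text (header row of descriptor names,
first column the compound id) with a JSON sidecar mapping descriptor name ->
descriptor class and compound id -> train/test role.  The missing marker in
files is the token ``NA``; in memory it is ``numpy.nan``.
"""

from __future__ import annotations

import csv
import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DESCRIPTOR_CLASSES",
    "POLYMORPHS",
    "CompoundRecord",
    "DescriptorMeta",
    "DescriptorMatrix",
    "ResponseSet",
    "PermeabilityMeasurement",
    "ParseReport",
    "PaperFixture",
    "compound_id",
    "percent_uptake",
    "apparent_permeability",
    "read_descriptor_table",
    "write_descriptor_table",
    "load_paper_fixture",
    "reference_descriptors",
    "split_train_test",
]

#: The six descriptor classes of the CODESSA taxonomy.
DESCRIPTOR_CLASSES = (
    "constitutional",
    "topological",
    "geometrical",
    "electrostatic",
    "thermodynamic",
    "quantum_chemical",
)

#: BCRP residue-482 polymorphs: wild type and the two mutants.
POLYMORPHS = ("482R", "482G", "482T")

ROLES = ("training", "test")

#: Missing-value token used in delimited files.
MISSING_TOKEN = "NA"


def compound_id(name: str) -> str:
    """Derive a compact unique id from a compound name.

    Lower-cases and collapses runs of non-alphanumeric characters, e.g.
    ``"Rhodamine 123" -> "rhodamine123"``.
    """
    return re.sub(r"[^a-z0-9]+", "", name.lower())


@dataclass(frozen=True)
class CompoundRecord:
    id: str
    name: str
    role: str
    pharm_class: str | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"role must be one of {ROLES}, got {self.role!r}")


@dataclass(frozen=True)
class DescriptorMeta:
    name: str
    dclass: str

    def __post_init__(self) -> None:
        if self.dclass not in DESCRIPTOR_CLASSES:
            raise ValueError(
                f"descriptor class must be one of {DESCRIPTOR_CLASSES}, "
                f"got {self.dclass!r}"
            )


@dataclass(frozen=True)
class ParseReport:
    """Counts of cells that had to be turned into the missing marker."""

    n_missing: int = 0
    n_unparseable: int = 0


@dataclass
class DescriptorMatrix:
    """Compounds x descriptors with class labels and NaN as missing marker."""

    compounds: list[CompoundRecord]
    descriptors: list[DescriptorMeta]
    values: pd.DataFrame  # index = compound ids, columns = descriptor names
    parse_report: ParseReport = field(default_factory=ParseReport)

    def __post_init__(self) -> None:
        ids = [c.id for c in self.compounds]
        names = [d.name for d in self.descriptors]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate compound ids: {dup}")
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate descriptor names: {dup}")
        if self.values.shape != (len(ids), len(names)):
            raise ValueError(
                f"value table shape {self.values.shape} does not match "
                f"{len(ids)} compounds x {len(names)} descriptors"
            )
        self.values = self.values.astype(float)
        self.values.index = pd.Index(ids, name="compound_id")
        self.values.columns = pd.Index(names)

    # -- convenience ------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def descriptor_names(self) -> list[str]:
        return [d.name for d in self.descriptors]

    @property
    def classes(self) -> dict[str, str]:
        return {d.name: d.dclass for d in self.descriptors}

    @property
    def roles(self) -> dict[str, str]:
        return {c.id: c.role for c in self.compounds}

    def training_values(self) -> pd.DataFrame:
        keep = [c.id for c in self.compounds if c.role == "training"]
        return self.values.loc[keep]

    def select_descriptors(self, names: Sequence[str]) -> "DescriptorMatrix":
        """A copy restricted to the given descriptors, preserving order."""
        nameset = set(names)
        missing = nameset - set(self.descriptor_names)
        if missing:
            raise KeyError(f"unknown descriptors: {sorted(missing)}")
        descs = [d for d in self.descriptors if d.name in nameset]
        return DescriptorMatrix(
            compounds=list(self.compounds),
            descriptors=descs,
            values=self.values[[d.name for d in descs]].copy(),
        )


@dataclass
class ResponseSet:
    """Per-compound uptake response for one BCRP polymorph.

    ``table`` columns:

    raw_rate
        uptake rate of Mitoxantrone in the presence of the compound
        (stored unit-agnostically, as printed).
    percent_printed
        the percent-of-control value as printed (integer).
    percent_recomputed
        round-half-up(100 * raw_rate / control_rate).
    inconsistent
        True where the printed percent disagrees with the recomputed one
        by more than 1 integer point.  Printed values are never corrected.
    """

    polymorph: str
    control_rate: float
    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.polymorph not in POLYMORPHS:
            raise ValueError(f"polymorph must be one of {POLYMORPHS}")
        if not self.control_rate > 0:
            raise ValueError("control_rate must be > 0")

    @property
    def percent(self) -> pd.Series:
        """Percent of control to use downstream (printed values, verbatim)."""
        return self.table["percent_printed"].astype(float)

    @property
    def flagged(self) -> list[str]:
        return list(self.table.index[self.table["inconsistent"]])


@dataclass(frozen=True)
class PermeabilityMeasurement:
    """Transwell permeability inputs: appearance rate, area, donor conc."""

    dQdt: float
    A: float
    D0: float

    def __post_init__(self) -> None:
        if not self.A > 0:
            raise ValueError("cross-sectional area A must be > 0")
        if not self.D0 > 0:
            raise ValueError("initial donor concentration D0 must be > 0")


# -- scalar formulas -------------------------------------------------------


def percent_uptake(raw_rate: float, control_rate: float) -> int:
    """Percent-of-control uptake, rounded half-up to an integer.

    100 * raw_rate / control_rate, as used to normalise Mitoxantrone uptake
    in the presence of a competing substrate against the no-substrate
    control.
    """
    if not (raw_rate > 0 and control_rate > 0):
        raise ValueError(
            "uptake rates must be strictly positive "
            f"(got raw={raw_rate}, control={control_rate})"
        )
    return int(math.floor(100.0 * raw_rate / control_rate + 0.5))


def apparent_permeability(m: PermeabilityMeasurement) -> float:
    """Apparent permeability Papp = (dQ/dt) / (A * D0), in cm/sec."""
    denom = m.A * m.D0
    if denom == 0:
        raise ValueError("A * D0 must be nonzero")
    return m.dQdt / denom


# -- descriptor table IO ---------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_descriptor_table(
    matrix: DescriptorMatrix,
    path: str | Path,
    delimiter: str = ",",
    sidecar: str | Path | None = None,
) -> None:
    """Write a descriptor matrix as delimited text plus a JSON sidecar.

    Finite values are written with ``repr`` (shortest exact decimal), so a
    write-then-read round trip is bit-for-bit.  NaN becomes the ``NA``
    token.
    """
    path = Path(path)
    sidecar = Path(sidecar) if sidecar is not None else _sidecar_path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(["compound_id", *matrix.descriptor_names])
        for cid, row in matrix.values.iterrows():
            cells = [
                MISSING_TOKEN if np.isnan(v) else repr(float(v))
                for v in row.to_numpy()
            ]
            writer.writerow([str(cid), *cells])
    meta = {
        "classes": matrix.classes,
        "roles": matrix.roles,
        "names": {c.id: c.name for c in matrix.compounds},
        "pharm_classes": {
            c.id: c.pharm_class for c in matrix.compounds if c.pharm_class
        },
    }
    with open(sidecar, "w") as fh:
        json.dump(meta, fh, indent=1)


def read_descriptor_table(
    path: str | Path,
    delimiter: str | None = None,
    sidecar: str | Path | None = None,
) -> DescriptorMatrix:
    """Read a delimited descriptor table and its JSON sidecar.

    The header row gives descriptor names; the first column is the compound
    id.  Blank or unparseable cells become the missing marker and are
    counted in ``matrix.parse_report``; the ``NA`` token is an intentional
    missing value and is not counted as unparseable.
    """
    path = Path(path)
    if delimiter is None:
        head = path.read_text().splitlines()[0]
        delimiter = "\t" if "\t" in head else ","
    sidecar = Path(sidecar) if sidecar is not None else _sidecar_path(path)
    meta: dict = {"classes": {}, "roles": {}, "names": {}, "pharm_classes": {}}
    if sidecar.exists():
        meta.update(json.loads(sidecar.read_text()))

    with open(path, newline="") as fh:
        header = next(csv.reader(fh, delimiter=delimiter))
    names = header[1:]
    if len(set(names)) != len(names):  # before pandas mangles duplicates
        dup = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate descriptor names in header: {dup}")
    raw = pd.read_csv(
        path, sep=delimiter, dtype=str, keep_default_na=False, index_col=0
    )
    raw.columns = names
    ids = list(raw.index.astype(str))
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate compound ids: {dup}")

    n_missing = 0
    n_unparseable = 0
    data = np.empty(raw.shape, dtype=float)
    for i, (_, row) in enumerate(raw.iterrows()):
        for j, cell in enumerate(row.to_numpy()):
            cell = cell.strip()
            if cell == MISSING_TOKEN or cell == "":
                data[i, j] = np.nan
                n_missing += 1
                continue
            try:
                data[i, j] = float(cell)
            except ValueError:
                data[i, j] = np.nan
                n_missing += 1
                n_unparseable += 1

    compounds = [
        CompoundRecord(
            id=cid,
            name=meta["names"].get(cid, cid),
            role=meta["roles"].get(cid, "training"),
            pharm_class=meta.get("pharm_classes", {}).get(cid),
        )
        for cid in ids
    ]
    descriptors = [
        DescriptorMeta(name=n, dclass=meta["classes"].get(n, "constitutional"))
        for n in names
    ]
    return DescriptorMatrix(
        compounds=compounds,
        descriptors=descriptors,
        values=pd.DataFrame(data, index=ids, columns=names),
        parse_report=ParseReport(n_missing=n_missing, n_unparseable=n_unparseable),
    )


# -- train/test split ------------------------------------------------------


def split_train_test(
    matrix: DescriptorMatrix, assignment: Mapping[str, str] | None = None
) -> tuple[DescriptorMatrix, DescriptorMatrix]:
    """Partition a matrix into (training, test) by compound role.

    ``assignment`` maps compound id -> role and defaults to the roles
    carried by the matrix itself.  Compound order and the descriptor list
    are preserved in both outputs.
    """
    roles = dict(assignment) if assignment is not None else matrix.roles
    missing = [c.id for c in matrix.compounds if c.id not in roles]
    if missing:
        raise KeyError(f"compounds missing from assignment: {missing}")

    def _part(role: str) -> DescriptorMatrix:
        comps = [
            CompoundRecord(c.id, c.name, role, c.pharm_class)
            for c in matrix.compounds
            if roles[c.id] == role
        ]
        return DescriptorMatrix(
            compounds=comps,
            descriptors=list(matrix.descriptors),
            values=matrix.values.loc[[c.id for c in comps]].copy(),
        )

    return _part("training"), _part("test")


# -- embedded uptake-rate fixture ------------------------------------------
#
# Mitoxantrone uptake rates in HEK cells expressing each BCRP residue-482
# polymorph, measured in the presence of each competing substrate.  Values
# are stored verbatim as printed (raw rate, integer percent of control) per
# polymorph in the order 482R, 482G, 482T.  The Mitoxantrone row is the
# no-competitor control.  Ketoconazole was assayed in both the training and
# the test set; the test-set row gets the id suffix "_test" to keep ids
# unique.

_CONTROLS = {"482R": 23.71, "482G": 27.43, "482T": 25.92}

_UPTAKE_ROWS: list[tuple[str, str, tuple, tuple, tuple]] = [
    ("Mitoxantrone", "training", (23.71, 100), (27.43, 100), (25.92, 100)),
    ("Caffeine", "training", (29.64, 125), (41.42, 151), (46.28, 140)),
    ("Ciprofloxacin", "training", (57.38, 242), (63.91, 233), (45.88, 177)),
    ("Cyclosporin", "training", (70.18, 296), (66.93, 244), (63.76, 246)),
    ("Diltiazem", "training", (55.95, 236), (59.52, 217), (32.40, 125)),
    ("Erythromycin", "training", (37.93, 160), (48.00, 175), (50.02, 193)),
    ("Estradiol", "training", (29.87, 126), (31.27, 114), (26.70, 103)),
    ("Febendazole", "training", (30.82, 130), (34.83, 127), (38.36, 148)),
    ("Ketoconazole", "training", (64.50, 272), (70.22, 256), (68.17, 263)),
    ("Nifedipine", "training", (38.17, 161), (42.52, 155), (38.36, 148)),
    ("Novobiocin", "training", (56.90, 240), (77.35, 282), (71.02, 274)),
    ("Quinidine", "training", (38.64, 163), (41.97, 153), (33.17, 128)),
    ("Raloxifene", "training", (46.47, 196), (55.95, 204), (23.58, 91)),
    ("Rhodamine 123", "training", (44.57, 188), (33.74, 123), (43.02, 166)),
    ("Riboflavin", "training", (41.25, 174), (35.92, 131), (36.80, 142)),
    ("Saquinavir", "training", (46.00, 194), (57.33, 209), (72.83, 281)),
    ("Tamoxifene", "training", (31.30, 132), (38.67, 141), (40.95, 158)),
    ("Verapamil", "training", (29.87, 126), (58.42, 213), (31.36, 121)),
    ("Acyclovir", "test", (50.26, 212), (66.91, 244), (68.95, 266)),
    ("Epinephrine", "test", (42.91, 181), (33.73, 123), (24.89, 115)),
    ("Foscarnet", "test", (29.87, 126), (30.45, 111), (33.17, 128)),
    ("FumitremorginC", "test", (26.76, 305), (79.82, 291), (84.75, 327)),
    ("Ketoconazole", "test", (64.02, 270), (70.77, 258), (68.17, 263)),
    ("PEITC", "test", (68.28, 288), (85.85, 313), (85.27, 329)),
    ("Quercetin", "test", (58.56, 247), (69.12, 252), (61.95, 239)),
]


@dataclass
class PaperFixture:
    """The embedded uptake table: 3 polymorph response sets + roles."""

    responses: dict[str, ResponseSet]
    compounds: list[CompoundRecord]

    @property
    def roles(self) -> dict[str, str]:
        return {c.id: c.role for c in self.compounds}

    @property
    def training_ids(self) -> list[str]:
        return [c.id for c in self.compounds if c.role == "training"]

    @property
    def test_ids(self) -> list[str]:
        return [c.id for c in self.compounds if c.role == "test"]


def load_paper_fixture(tolerance: int = 1) -> PaperFixture:
    """Load the embedded per-polymorph uptake table.

    Returns 18 training rows (17 competing substrates + the Mitoxantrone
    control) and 7 test rows for each polymorph.  Each cell's printed
    percent is checked against ``percent_uptake`` of its raw rate and the
    polymorph control; disagreement beyond ``tolerance`` integer points
    sets the ``inconsistent`` flag (the printed value is kept verbatim).
    """
    compounds = []
    seen: set[str] = set()
    for name, role, *_ in _UPTAKE_ROWS:
        cid = compound_id(name)
        if cid in seen:
            cid = f"{cid}_{role}"
        seen.add(cid)
        compounds.append(CompoundRecord(id=cid, name=name, role=role))

    responses = {}
    for p_idx, polymorph in enumerate(POLYMORPHS):
        control = _CONTROLS[polymorph]
        recs = []
        for comp, row in zip(compounds, _UPTAKE_ROWS):
            raw, printed = row[2 + p_idx]
            recomputed = percent_uptake(raw, control)
            recs.append(
                {
                    "compound_id": comp.id,
                    "raw_rate": raw,
                    "percent_printed": printed,
                    "percent_recomputed": recomputed,
                    "inconsistent": abs(recomputed - printed) > tolerance,
                }
            )
        table = pd.DataFrame(recs).set_index("compound_id")
        responses[polymorph] = ResponseSet(
            polymorph=polymorph, control_rate=control, table=table
        )
    return PaperFixture(responses=responses, compounds=compounds)


# -- reference descriptor taxonomy -----------------------------------------
#
# The 26 named descriptors used for model identification, grouped by class.
# The quantum-chemical list contains two distinct "ESP-Max net atomic
# charge" entries; the second is disambiguated with the suffix "2" as it
# appears in the fitted-model listings.

_REFERENCE_TAXONOMY: list[tuple[str, tuple[str, ...]]] = [
    (
        "constitutional",
        (
            "Number of double bonds",
            "Number of aromatic bonds",
            "Number of Oxygen atoms",
            "Average distance sum connectivity index",
            "ESP-RNCS: Relative negative charged SA (SAMNEG*RNCG)",
            "ESP-RPCS Relative positive charge SA (QMPOS/QTPLUS) [Zefirov's PC]",
            "WPSA3 weighted PPSA (PPSA3*TMSA/1000) [Zefirov's PC]",
            "ESP-FPSA-1 Fractional PPSA (PPSA-1/TMSA)",
        ),
    ),
    (
        "thermodynamic",
        ("Translational Entropy", "Total Entropy", "Total Enthalpy"),
    ),
    (
        "electrostatic",
        (
            "Max partial charge",
            "Max partial charge for a hydrogen atom",
            "Max partial charge for a carbon atom",
        ),
    ),
    (
        "quantum_chemical",
        (
            "Max atomic orbital electronic population",
            "ESP-Max net atomic charge",
            "Avg electroph. react. index for a O atom",
            "Max 1-electron react. index for a C atom",
            "Max SIGMA-PI bond order",
            "ESP-Max net atomic charge 2",
            "ESP-Max net atomic charge for a N atom",
            "min(#HA, #HD) [Quantum-Chemical PC]",
            "Min e-n attraction for a C-C bond",
            "Min e-n attraction for a C-H bond",
            "HOMO-1 energy",
            "LUMO + 1 energy",
        ),
    ),
]


def reference_descriptors() -> list[DescriptorMeta]:
    """The 26 class-labelled descriptors of the reference taxonomy."""
    return [
        DescriptorMeta(name=name, dclass=dclass)
        for dclass, names in _REFERENCE_TAXONOMY
        for name in names
    ]
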