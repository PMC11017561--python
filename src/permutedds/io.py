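"""Reading and writing the delimited-text formats the pipeline consumes.

All formats are plain UTF-8 CSV with a header row:

* drug table: ``drug_id,smiles``
* synergy table: ``drug_a,drug_b,cell_line,score``
* expression / mutation matrix: first column ``cell_id``, remaining columns
  gene symbols
* landmark gene list: one symbol per line (no header)
* fingerprint table: ``drug_id`` followed by one 0/1 column per bit
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .experiments import SynergyRecord
from .fingerprints import FingerprintVector


def read_drug_table(path) -> list[tuple[str, str]]:
    frame = pd.read_csv(path, dtype=str)
    if not {"drug_id", "smiles"} <= set(frame.columns):
        raise ValueError("drug table needs columns drug_id, smiles")
    return list(frame[["drug_id", "smiles"]].itertuples(index=False, name=None))


def write_drug_table(drugs: list[tuple[str, str]], path) -> None:
    pd.DataFrame(drugs, columns=["drug_id", "smiles"]).to_csv(path, index=False)


def read_synergy_table(path) -> list[SynergyRecord]:
    frame = pd.read_csv(path)
    required = {"drug_a", "drug_b", "cell_line", "score"}
    if not required <= set(frame.columns):
        raise ValueError(f"synergy table needs columns {sorted(required)}")
    return [
        SynergyRecord(str(r.drug_a), str(r.drug_b), str(r.cell_line), float(r.score))
        for r in frame.itertuples(index=False)
    ]


def write_synergy_table(records: list[SynergyRecord], path) -> None:
    pd.DataFrame(
        [(r.drug_a, r.drug_b, r.cell_id, r.score) for r in records],
        columns=["drug_a", "drug_b", "cell_line", "score"],
    ).to_csv(path, index=False)


def read_profile_matrix(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    first = frame.columns[0]
    return frame.set_index(first).astype(float)


def write_profile_matrix(matrix: pd.DataFrame, path) -> None:
    matrix.rename_axis("cell_id").to_csv(path)


def read_landmark_list(path) -> list[str]:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_landmark_list(genes, path) -> None:
    with open(path, "w") as fh:
        fh.writelines(f"{g}\n" for g in genes)


def write_fingerprint_table(vectors: dict[str, FingerprintVector], path) -> None:
    ids = sorted(vectors)
    arr = np.stack([vectors[d].values for d in ids])
    frame = pd.DataFrame(arr, index=pd.Index(ids, name="drug_id"))
    frame.columns = [f"bit{j}" for j in range(arr.shape[1])]
    frame.to_csv(path)


def read_fingerprint_table(path, kind: str) -> dict[str, FingerprintVector]:
    frame = pd.read_csv(path).set_index("drug_id")
    return {
        str(d): FingerprintVector(kind=kind, values=row.to_numpy(dtype=np.uint8))
        for d, row in frame.iterrows()
    }
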