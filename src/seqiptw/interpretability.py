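"""Confounder attribution from [CLS] attention.

For BERT propensity models, the attention row of the [CLS] query at the last
encoder layer (averaged over heads) indicates which input positions the
sequence summary attends to.  Grouping positions into *confounder* tokens
(occurrences of the scenario's target codes), *all other* tokens, and the
[CLS] self-position, and comparing group means, quantifies whether the model
discovered the confounding variables without being told about them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import ClaimsDataset, PatientSequence
from .models import BertPropensity, forward_propensity

__all__ = ["AttentionSummary", "cls_attention_row", "group_attention", "export_heatmap"]


@dataclass
class AttentionSummary:
    model_kind: str
    mean_confounder: float
    mean_other: float
    mean_cls: float
    per_patient: pd.DataFrame  # columns: confounder, other, cls (NaN where group empty)
    n_without_confounder: int

    def __str__(self) -> str:
        return (
            f"[CLS] attention ({self.model_kind}): confounders {self.mean_confounder:.3f}, "
            f"all other {self.mean_other:.3f}, [CLS] {self.mean_cls:.3f} "
            f"({self.n_without_confounder} patients without confounder positions excluded)"
        )


def _check_bert(model) -> BertPropensity:
    if not isinstance(model, BertPropensity):
        raise TypeError(
            f"attention attribution needs a BERT model, got {type(model).__name__}"
        )
    return model


def cls_attention_row(model, seq: PatientSequence) -> np.ndarray:
    """Last-layer, head-averaged attention row for the [CLS] query of one
    patient; one weight per input position, summing to 1."""
    model = _check_bert(model)
    forward_propensity(model, [seq])
    last = model.attention_maps()[-1]  # (1, H, L, L)
    return last[0].mean(axis=0)[0]


def _confounder_positions(model: BertPropensity, seq: PatientSequence,
                          confounder_codes: set[int]) -> np.ndarray:
    """Token indices (into the model input, [CLS]=0) carrying confounder codes."""
    hits = []
    if model.cfg.kind == "bert_code":
        tok = 1
        for r in seq.records:
            for c in sorted(r.codes):
                if c in confounder_codes:
                    hits.append(tok)
                tok += 1
    else:  # bert_record: one token per record
        for r in seq.records:
            if r.codes & confounder_codes:
                hits.append(r.t)  # token index == position t
    return np.array(hits, dtype=np.int64)


def group_attention(ds: ClaimsDataset, model, confounder_codes=None,
                    batch_size: int = 32) -> AttentionSummary:
    """Average [CLS]-attention per position group, patient-level then across
    patients.  Patients with no confounder position contribute to the other
    and [CLS] groups only."""
    model = _check_bert(model)
    if confounder_codes is None:
        confounder_codes = ds.metadata.get("target_codes")
        if confounder_codes is None:
            raise ValueError("no confounder codes given and none in dataset metadata")
    codes = set(int(c) for c in confounder_codes)

    rows = []
    for start in range(0, len(ds), batch_size):
        batch = ds.patients[start : start + batch_size]
        forward_propensity(model, batch)
        attn = model.attention_maps()[-1]  # (B, H, L, L)
        cls_rows = attn.mean(axis=1)[:, 0, :]  # head-averaged [CLS] query rows
        for i, seq in enumerate(batch):
            length = model.build_input(seq).length
            w = cls_rows[i, :length]
            conf = _confounder_positions(model, seq, codes)
            mask = np.zeros(length, dtype=bool)
            mask[conf] = True
            other = ~mask
            other[0] = False  # [CLS] is its own group
            rows.append(
                {
                    "confounder": float(w[conf].mean()) if conf.size else np.nan,
                    "other": float(w[other].mean()) if other.any() else np.nan,
                    "cls": float(w[0]),
                }
            )
    per_patient = pd.DataFrame(rows)
    return AttentionSummary(
        model_kind=model.cfg.kind,
        mean_confounder=float(per_patient["confounder"].mean()),
        mean_other=float(per_patient["other"].mean()),
        mean_cls=float(per_patient["cls"].mean()),
        per_patient=per_patient,
        n_without_confounder=int(per_patient["confounder"].isna().sum()),
    )


def export_heatmap(ds: ClaimsDataset, model, patient_indices, csv_path, png_path=None):
    """Position x patient [CLS]-attention matrix as CSV (and PNG heatmap)."""
    model = _check_bert(model)
    rows = {}
    for i in patient_indices:
        seq = ds.patients[i]
        rows[seq.id] = cls_attention_row(model, seq)
    L = max(len(v) for v in rows.values())
    mat = np.full((L, len(rows)), np.nan)
    for j, (pid, v) in enumerate(rows.items()):
        mat[: len(v), j] = v
    df = pd.DataFrame(mat, columns=list(rows))
    df.index.name = "position"
    df.to_csv(csv_path)
    if png_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(2 + 0.5 * len(rows), 4))
        im = ax.imshow(mat, aspect="auto", cmap="Greys")
        ax.set_xlabel("patient")
        ax.set_ylabel("input position")
        fig.colorbar(im, ax=ax, label="[CLS] attention")
        fig.tight_layout()
        fig.savefig(png_path, dpi=120)
        plt.close(fig)
    return df
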