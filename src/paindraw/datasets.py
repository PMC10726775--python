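"""Bundled questionnaire response counts from the body-outline survey.

A survey of 49 female endometriosis patients compared two body-outline
variants for pain drawings: one group received sheets with a *sexless*
(gender-neutral) outline, the other a *female* outline.  Five questions
probed suitability of the outline, perceived sex neutrality, the
anatomical features used to judge sex, and how much outline/sex mismatch
matters.  The full response counts are reproduced here so the exact-test
battery is runnable without any external data.

Row orientation per table follows the orientation used in the original
analysis (it differs between questions; odds ratios are reported with
explicit row/column labels for this reason).

The question-5 counts are bundled for completeness but flagged: the
odds ratio originally reported for them (0.473) is not reproducible from
these counts under either row orientation (they give 1.430, or 0.699
with rows swapped), so question 5 is excluded from validation targets.
"""

from __future__ import annotations

from .cohort_stats import ContingencyTable

__all__ = ["load_questionnaire_counts", "QUESTION_TEXT"]

QUESTION_TEXT = {
    "q1_suitability": "Is the pain drawing suitable for drawing pain on your body?",
    "q2_sexless": "Do you consider the body outline sexless?",
    "q3_features": "Which characteristics identify the outline as sexless or female?",
    "q4_importance": "How important is it that the outline's sex is adapted?",
    "q5_disturbance": "How much does a non-sex-adapted outline bother you?",
}


def load_questionnaire_counts() -> dict[str, ContingencyTable]:
    """Response-count tables for the five survey questions."""
    return {
        "q1_suitability": ContingencyTable(
            row_labels=["sexless", "female"],
            col_labels=["yes", "no"],
            counts=[[21, 2], [22, 3]],
            name="q1_suitability",
        ),
        "q2_sexless": ContingencyTable(
            row_labels=["sexless", "female"],
            col_labels=["yes", "no"],
            counts=[[14, 8], [9, 16]],
            name="q2_sexless",
        ),
        "q3_features": ContingencyTable(
            row_labels=["sexless", "female"],
            col_labels=["head", "shoulders", "arms", "legs", "buttocks",
                        "abdomen", "waist", "chest", "feet"],
            counts=[[6, 5, 5, 5, 6, 5, 10, 14, 3],
                    [3, 2, 0, 2, 2, 0, 8, 12, 1]],
            name="q3_features",
        ),
        "q4_importance": ContingencyTable(
            row_labels=["female", "sexless"],
            col_labels=["important", "unimportant", "no opinion"],
            counts=[[11, 9, 5], [14, 9, 0]],
            name="q4_importance",
        ),
        # flagged: see module docstring
        "q5_disturbance": ContingencyTable(
            row_labels=["sexless", "female"],
            col_labels=["bothers me", "doesn't bother me", "no opinion"],
            counts=[[8, 9, 6], [8, 13, 4]],
            name="q5_disturbance",
        ),
    }
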