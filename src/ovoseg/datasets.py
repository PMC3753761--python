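"""Reference evaluation data shipped with the package.

The two confusion matrices below are the published 8-class evaluation
results of the chick long-bone SVM study this pipeline re-implements:
one from 10-fold cross-validation on the annotated training corpus
(group 1, 2951 object instances from 27 eggs at incubation days 13-19),
one from applying the trained model to the unannotated test corpus
(group 2, 1203 instances from 4 eggs scanned daily at days 13-15).
They serve as worked-example inputs for the metrics machinery.
"""

from __future__ import annotations

import numpy as np

from .evaluation import ConfusionMatrix
from .model import ANNOTATION_CLASSES

__all__ = ["load_group1_confusion", "load_group2_confusion"]

# rows = truth, columns = prediction; class order: humerus, radius, ulna,
# carpometacarpus, femur, tibiotarsus, tarsometatarsus, NOI
_GROUP1 = [
    [48, 0, 0, 0, 0, 0, 0, 3],
    [0, 39, 1, 0, 0, 0, 0, 2],
    [1, 0, 45, 0, 0, 0, 0, 3],
    [1, 0, 1, 45, 0, 0, 0, 5],
    [0, 0, 0, 0, 51, 0, 0, 0],
    [0, 0, 0, 0, 1, 49, 2, 1],
    [0, 0, 0, 0, 1, 1, 48, 1],
    [7, 3, 1, 5, 0, 0, 0, 2586],
]

_GROUP2 = [
    [21, 0, 0, 0, 0, 0, 0, 3],
    [0, 15, 0, 0, 0, 0, 0, 1],
    [0, 2, 19, 0, 0, 0, 0, 1],
    [0, 0, 1, 21, 0, 0, 0, 2],
    [0, 0, 0, 0, 23, 0, 0, 1],
    [0, 0, 0, 0, 0, 21, 1, 2],
    [0, 0, 0, 0, 0, 0, 19, 2],
    [0, 0, 1, 0, 0, 0, 0, 1047],
]


def load_group1_confusion() -> ConfusionMatrix:
    """Training-corpus 10-fold CV confusion matrix (2951 instances)."""
    return ConfusionMatrix(np.array(_GROUP1), ANNOTATION_CLASSES)


def load_group2_confusion() -> ConfusionMatrix:
    """Test-corpus confusion matrix (1203 instances)."""
    return ConfusionMatrix(np.array(_GROUP2), ANNOTATION_CLASSES)
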