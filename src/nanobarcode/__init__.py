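"""Pixel-wise identification of combinatorial protein nanobarcodes.

Proteins tagged with on/off combinations of n epitopes (2**n - 1 codes for
n slots) are imaged in a single multichannel acquisition; a residual
multi-branch classifier maps each pixel's channel intensities to a barcode
class or blank.  The package covers the full loop: simulation of
single-transfect fields, kernel-PCA foreground masking, supervised training
with contrast augmentation, whole-image inference with self-supervised
contrast adaptation, false-color rendering, and evaluation.
"""

__version__ = "0.1.0"

from .barcodes import (
    Barcode,
    SpectralResponseMatrix,
    barcode_signature,
    default_response_matrix,
    enumerate_barcodes,
)
from .evaluation import (
    MetricsReport,
    ablation_study,
    compute_metrics,
    confusion_from_pairs,
    embed_pixels,
    false_call_shares,
)
from .inference import (
    ContrastModifier,
    ProteinMap,
    classify_image,
    fit_contrast_modifier,
    image_precision,
    mean_output_entropy,
    render_false_color,
)
from .io import RunConfig, read_stack, write_stack
from .masking import (
    ForegroundMask,
    MaskingModel,
    PixelDataset,
    compute_mask,
    fit_masking_model,
    gather_pixels,
)
from .network import (
    NetworkConfig,
    ResidualClassifier,
    build_classifier,
    forward,
    nll_loss,
    softmax,
)
from .simulate import (
    AcquisitionScheme,
    ChannelStack,
    GroundTruth,
    SimConfig,
    default_scheme,
    simulate_dataset,
    simulate_image,
)
from .training import (
    TrainConfig,
    TrainingHistory,
    augment_contrast,
    evaluate_holdout,
    learning_rate_at,
    split_dataset,
    train,
)

__all__ = [name for name in dir() if not name.startswith("_")]
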