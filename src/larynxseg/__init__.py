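"""Transformer-based segmentation pipeline for laryngeal endoscopy images.

Segments two laryngeal structures — the trachea (the dark airway opening,
class 1) and the supraglottis (the surrounding mucosal ring, class 2) —
against background (class 0), with a seeded synthetic-scene generator so
the whole pipeline is testable without patient data.
"""

from . import evaluation, model, nn, pipeline, postprocess, preprocess, synthetic, train
from .evaluation import MetricsReport, TimingReport, dice, evaluate, time_inference
from .model import ModelConfig, SegmentationModel, load_checkpoint, predict, save_checkpoint
from .pipeline import AblationReport, ExperimentConfig, ablation_augmentation, run_experiment
from .postprocess import PostConfig, postprocess as refine_mask
from .preprocess import AugmentConfig, DatasetSplit, SplitFractions, augment, split_dataset
from .synthetic import Sample, SceneParams, generate_dataset, render_sample, sample_scene_params
from .train import TrainConfig, TrainLog, cross_entropy_loss, fit

__version__ = "0.1.0"
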