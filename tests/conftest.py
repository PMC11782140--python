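import numpy as np
import pytest

from resteeg.io import ChannelLayout, EpochedRecording, Recording, SubjectMeta


def make_recording(
    data: np.ndarray,
    fs: float = 250.0,
    subject_id: str = "s01",
    condition: str = "EC",
    names: tuple[str, ...] | None = None,
) -> Recording:
    layout = ChannelLayout(names) if names is not None else ChannelLayout()
    return Recording(
        subject_id=subject_id, condition=condition, fs=fs, data=np.asarray(data, float),
        layout=layout,
    )


def epoched_from_channels(
    channels: list[np.ndarray],
    fs: float = 250.0,
    epoch_length_s: float = 4.0,
    names: tuple[str, ...] | None = None,
    condition: str = "EC",
) -> EpochedRecording:
    """Cut equal-length continuous channels into consecutive epochs."""
    x = np.stack([np.asarray(c, float) for c in channels])
    n_per = int(round(epoch_length_s * fs))
    n_ep = x.shape[1] // n_per
    epochs = (
        x[:, : n_ep * n_per].reshape(x.shape[0], n_ep, n_per).transpose(1, 0, 2)
    )
    if names is None:
        names = tuple("ABCDEFGH"[: x.shape[0]]) if x.shape[0] != 8 else None
    layout = ChannelLayout(names) if names is not None else ChannelLayout()
    return EpochedRecording(
        subject_id="s01", condition=condition, fs=fs, epochs=epochs,
        epoch_length_s=epoch_length_s, layout=layout,
    )


@pytest.fixture
def meta_pair() -> list[SubjectMeta]:
    return [
        SubjectMeta("AD01", "AD", 72.0, "F", 3, "R"),
        SubjectMeta("AD02", "AD", 68.0, "M", 2, "R"),
        SubjectMeta("HC01", "HC", 65.0, "F", 4, "R"),
        SubjectMeta("HC02", "HC", 61.0, "M", 3, "R"),
    ]
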