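"""Canonical channel ordering and named sensor groups.

The trial matrix has 35 columns: 8 surface-EMG channels followed by three
9-axis IMU units.  EMG electrodes sit bilaterally over the tibialis anterior
(TA), gastrocnemius medialis (GM), gastrocnemius lateralis (GL) and soleus
(SOL); IMUs sit on the left shank, right shank and right foot, each unit
ordered accelerometer xyz, gyroscope xyz, magnetometer xyz.

The column order is a package convention (fixed so that channel-group
ablation and single-leg subsetting are well defined) and is used everywhere:
the generator, trial files, and model input subsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

EMG_CHANNELS: tuple[str, ...] = (
    "emg_l_ta", "emg_l_gm", "emg_l_gl", "emg_l_sol",
    "emg_r_ta", "emg_r_gm", "emg_r_gl", "emg_r_sol",
)

IMU_PLACEMENTS: tuple[str, ...] = ("left_shank", "right_shank", "right_foot")

IMU_AXES: tuple[str, ...] = (
    "acc_x", "acc_y", "acc_z",
    "gyr_x", "gyr_y", "gyr_z",
    "mag_x", "mag_y", "mag_z",
)


def _imu_names(placement: str) -> list[str]:
    return [f"imu_{placement}_{axis}" for axis in IMU_AXES]


@dataclass(frozen=True)
class ChannelLayout:
    """Ordered channel names plus named index groups for subsetting.

    Groups (sizes): emg_left (4), emg_right (4), imu_left_shank (9),
    imu_right_shank (9), imu_right_foot (9), imu_right_leg (18),
    leg_left (13), leg_right (22), emg_all (8), imu_all (27), all (35).
    """

    names: tuple[str, ...] = field(default_factory=tuple)
    groups: dict[str, tuple[int, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.names:
            names = list(EMG_CHANNELS)
            for placement in IMU_PLACEMENTS:
                names.extend(_imu_names(placement))
            object.__setattr__(self, "names", tuple(names))
        if not self.groups:
            emg_left = tuple(range(0, 4))
            emg_right = tuple(range(4, 8))
            imu_ls = tuple(range(8, 17))
            imu_rs = tuple(range(17, 26))
            imu_rf = tuple(range(26, 35))
            groups = {
                "emg_left": emg_left,
                "emg_right": emg_right,
                "imu_left_shank": imu_ls,
                "imu_right_shank": imu_rs,
                "imu_right_foot": imu_rf,
                "imu_right_leg": imu_rs + imu_rf,
                "leg_left": emg_left + imu_ls,
                "leg_right": emg_right + imu_rs + imu_rf,
                "emg_all": emg_left + emg_right,
                "imu_all": imu_ls + imu_rs + imu_rf,
                "all": tuple(range(35)),
            }
            object.__setattr__(self, "groups", groups)
        self._validate()

    def _validate(self) -> None:
        if len(self.names) != len(set(self.names)):
            raise ValueError("channel names must be unique")
        n = len(self.names)
        for gname, idx in self.groups.items():
            if any(i < 0 or i >= n for i in idx):
                raise ValueError(f"group {gname!r} indexes outside 0..{n - 1}")
            if len(idx) != len(set(idx)):
                raise ValueError(f"group {gname!r} contains duplicate indices")

    @property
    def n_channels(self) -> int:
        return len(self.names)

    def group(self, name: str) -> tuple[int, ...]:
        """Return the column indices of a named group.

        Raises ``KeyError`` listing the valid names for unknown groups.
        """
        try:
            return self.groups[name]
        except KeyError:
            valid = ", ".join(sorted(self.groups))
            raise KeyError(
                f"unknown channel group {name!r}; valid groups: {valid}"
            ) from None

    def group_names(self, name: str) -> list[str]:
        return [self.names[i] for i in self.group(name)]


DEFAULT_LAYOUT = ChannelLayout()
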