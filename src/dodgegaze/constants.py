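"""Fixed geometry and timing constants of the Dodge Asteroids setup.

Everything here is a property of the apparatus or the game engine, not a
tunable parameter: the 60-FPS logical clock, the 720-px-wide scrolling
environment, the fixed on-screen ship position, and the pixel↔visual-degree
conversion of the recording geometry.
"""

from __future__ import annotations

from dataclasses import dataclass

# --- environment frame (world coordinates, y grows downward) ---
ENV_WIDTH_PX = 720
SHIP_SIZE_PX = 36
OBSTACLE_SIZE_PX = 36
FALL_PX_PER_FRAME = 6        # automatic vertical progress each frame
KEY_STEP_PX = 6              # nominal horizontal step while a key is down
DRIFT_PX_PER_FRAME = 3       # lateral push inside an active drift section
DRIFT_SPAN_PX = 270
DRIFT_BAR_OFFSET_PX = 45
DRIFT_BAR_WIDTH_PX = 18
FPS = 60

VALID_LENGTHS_PX = (9000, 13500, 18000)

# --- screen frame (what the participant sees) ---
SCREEN_W_PX = 1920
SCREEN_H_PX = 1080
SHIP_SCREEN_X = 954          # top-left corner of the ship sprite on screen
SHIP_SCREEN_Y = 270
OCCLUDER_HEIGHT_PX = 270     # gray bar along the bottom of the screen
VISIBLE_HEIGHT_PX = SCREEN_H_PX - OCCLUDER_HEIGHT_PX  # 810

SHIP_SCREEN_CENTER = (SHIP_SCREEN_X + SHIP_SIZE_PX / 2,
                      SHIP_SCREEN_Y + SHIP_SIZE_PX / 2)

# --- eye tracking ---
SAMPLE_RATE_HZ = 2000
SAMPLE_DT_S = 1.0 / SAMPLE_RATE_HZ
# 1.25 px of screen travel corresponds to 0.026 degrees of visual angle
DEG_PER_PX = 0.026 / 1.25


@dataclass(frozen=True)
class ScreenMap:
    """Mapping between environment and screen coordinates.

    The ship sprite is pinned to a fixed screen position; the world scrolls
    around it.  An object at environment position ``p`` appears on screen at
    ``ship_screen_topleft + (p - ship_env_topleft)``.
    """

    screen_w: int = SCREEN_W_PX
    screen_h: int = SCREEN_H_PX
    ship_screen_x: int = SHIP_SCREEN_X
    ship_screen_y: int = SHIP_SCREEN_Y
    occluder_height: int = OCCLUDER_HEIGHT_PX
    fps: int = FPS

    @property
    def visible_height(self) -> int:
        return self.screen_h - self.occluder_height

    @property
    def ship_center(self) -> tuple[float, float]:
        return (self.ship_screen_x + SHIP_SIZE_PX / 2,
                self.ship_screen_y + SHIP_SIZE_PX / 2)

    def env_to_screen(self, env_x: float, env_y: float,
                      ship_env_x: float, ship_env_y: float) -> tuple[float, float]:
        return (self.ship_screen_x + (env_x - ship_env_x),
                self.ship_screen_y + (env_y - ship_env_y))


DEFAULT_SCREEN_MAP = ScreenMap()
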