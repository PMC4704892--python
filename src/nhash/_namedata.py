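"""Bundled name-frequency tables for the synthetic-cohort generator.

Weights are approximate occurrences per 100,000 population for common
United States surnames and given names, in the spirit of the public
census rank tables. The absolute scale is irrelevant — sampling uses the
weights proportionally — but the heavy skew toward a small set of very
common names is the feature being emulated, since it is what depresses
the name component of the identifier space below its uniform size.
Studies wanting the full published rank lists can load their own
two-column (name, weight) file instead; see
:func:`nhash.simulate.load_name_table`.
"""

SURNAMES: list[tuple[str, float]] = [
    ("SMITH", 828), ("JOHNSON", 655), ("WILLIAMS", 540), ("BROWN", 479),
    ("JONES", 475), ("GARCIA", 395), ("MILLER", 393), ("DAVIS", 361),
    ("RODRIGUEZ", 354), ("MARTINEZ", 343), ("HERNANDEZ", 318), ("LOPEZ", 290),
    ("GONZALEZ", 286), ("WILSON", 272), ("ANDERSON", 262), ("THOMAS", 255),
    ("TAYLOR", 252), ("MOORE", 246), ("JACKSON", 236), ("MARTIN", 225),
    ("LEE", 218), ("PEREZ", 213), ("THOMPSON", 210), ("WHITE", 208),
    ("HARRIS", 203), ("SANCHEZ", 200), ("CLARK", 187), ("RAMIREZ", 184),
    ("LEWIS", 180), ("ROBINSON", 177), ("WALKER", 176), ("YOUNG", 168),
    ("ALLEN", 163), ("KING", 161), ("WRIGHT", 160), ("SCOTT", 158),
    ("TORRES", 157), ("NGUYEN", 156), ("HILL", 155), ("FLORES", 152),
    ("GREEN", 150), ("ADAMS", 147), ("NELSON", 145), ("BAKER", 144),
    ("HALL", 143), ("RIVERA", 141), ("CAMPBELL", 140), ("MITCHELL", 138),
    ("CARTER", 136), ("ROBERTS", 134), ("GOMEZ", 132), ("PHILLIPS", 131),
    ("EVANS", 130), ("TURNER", 128), ("DIAZ", 127), ("PARKER", 124),
    ("CRUZ", 122), ("EDWARDS", 121), ("COLLINS", 120), ("REYES", 119),
    ("STEWART", 118), ("MORRIS", 116), ("MORALES", 115), ("MURPHY", 114),
    ("COOK", 112), ("ROGERS", 111), ("GUTIERREZ", 110), ("ORTIZ", 109),
    ("MORGAN", 108), ("COOPER", 107), ("PETERSON", 106), ("BAILEY", 105),
    ("REED", 104), ("KELLY", 103), ("HOWARD", 102), ("RAMOS", 101),
    ("KIM", 100), ("COX", 99), ("WARD", 98), ("RICHARDSON", 97),
    ("WATSON", 96), ("BROOKS", 95), ("CHAVEZ", 94), ("WOOD", 93),
    ("JAMES", 92), ("BENNETT", 91), ("GRAY", 90), ("MENDOZA", 89),
    ("RUIZ", 88), ("HUGHES", 87), ("PRICE", 86), ("ALVAREZ", 85),
    ("CASTILLO", 84), ("SANDERS", 83), ("PATEL", 82), ("MYERS", 81),
    ("LONG", 80), ("ROSS", 79), ("FOSTER", 78), ("JIMENEZ", 77),
    ("POWELL", 76), ("JENKINS", 75), ("PERRY", 74), ("RUSSELL", 73),
    ("SULLIVAN", 72), ("BELL", 71), ("COLEMAN", 70), ("BUTLER", 69),
    ("HENDERSON", 68), ("BARNES", 67), ("GONZALES", 66), ("FISHER", 65),
    ("VASQUEZ", 64), ("SIMMONS", 63), ("ROMERO", 62), ("JORDAN", 61),
    ("PATTERSON", 60), ("ALEXANDER", 59), ("HAMILTON", 58), ("GRAHAM", 57),
    ("REYNOLDS", 56), ("GRIFFIN", 55), ("WALLACE", 54), ("MORENO", 53),
    ("WEST", 52), ("COLE", 51), ("HAYES", 50), ("BRYANT", 49),
    ("HERRERA", 48), ("GIBSON", 47), ("ELLIS", 46), ("TRAN", 45),
    ("MEDINA", 44), ("AGUILAR", 43), ("STEVENS", 42), ("MURRAY", 41),
    ("FORD", 40), ("CASTRO", 39), ("MARSHALL", 38), ("OWENS", 37),
    ("HARRISON", 36), ("FERNANDEZ", 35), ("MCDONALD", 34), ("WOODS", 33),
    ("WASHINGTON", 32), ("KENNEDY", 31), ("WELLS", 30), ("VARGAS", 29),
    ("HENRY", 28), ("CHEN", 27), ("FREEMAN", 26), ("WEBB", 25),
    ("TUCKER", 24), ("GUZMAN", 23), ("BURNS", 22), ("CRAWFORD", 21),
    ("OLSON", 20), ("SIMPSON", 19), ("PORTER", 18), ("HUNTER", 17),
    ("GORDON", 16), ("MENDEZ", 15), ("SILVA", 14), ("SHAW", 13),
    ("SNYDER", 12), ("MASON", 11), ("DIXON", 10), ("MUNOZ", 9),
    ("HUNT", 8), ("HICKS", 7), ("HOLMES", 6), ("PALMER", 5),
]

FIRST_NAMES: list[tuple[str, float]] = [
    ("JAMES", 3318), ("MARY", 2629), ("JOHN", 3271), ("PATRICIA", 1073),
    ("ROBERT", 3143), ("JENNIFER", 1467), ("MICHAEL", 4350), ("LINDA", 1035),
    ("WILLIAM", 2451), ("ELIZABETH", 1436), ("DAVID", 3611), ("BARBARA", 980),
    ("RICHARD", 1703), ("SUSAN", 1103), ("JOSEPH", 1404), ("JESSICA", 1045),
    ("THOMAS", 1380), ("SARAH", 1087), ("CHARLES", 1228), ("KAREN", 986),
    ("CHRISTOPHER", 2032), ("NANCY", 869), ("DANIEL", 1893), ("LISA", 965),
    ("MATTHEW", 1589), ("BETTY", 666), ("ANTHONY", 1404), ("MARGARET", 768),
    ("MARK", 1346), ("SANDRA", 873), ("DONALD", 931), ("ASHLEY", 843),
    ("STEVEN", 1281), ("KIMBERLY", 889), ("PAUL", 1087), ("EMILY", 840),
    ("ANDREW", 1247), ("DONNA", 583), ("JOSHUA", 1175), ("MICHELLE", 971),
    ("KENNETH", 826), ("DOROTHY", 607), ("KEVIN", 1170), ("CAROL", 645),
    ("BRIAN", 1160), ("AMANDA", 863), ("GEORGE", 786), ("MELISSA", 953),
    ("EDWARD", 792), ("DEBORAH", 739), ("RONALD", 730), ("STEPHANIE", 878),
    ("TIMOTHY", 1069), ("REBECCA", 835), ("JASON", 1242), ("SHARON", 688),
    ("JEFFREY", 975), ("LAURA", 712), ("RYAN", 1073), ("CYNTHIA", 723),
    ("JACOB", 933), ("KATHLEEN", 689), ("GARY", 750), ("AMY", 866),
    ("NICHOLAS", 1024), ("ANGELA", 833), ("ERIC", 1023), ("SHIRLEY", 482),
    ("JONATHAN", 923), ("ANNA", 616), ("STEPHEN", 774), ("BRENDA", 612),
    ("LARRY", 598), ("PAMELA", 622), ("JUSTIN", 983), ("EMMA", 483),
    ("SCOTT", 852), ("NICOLE", 806), ("BRANDON", 933), ("HELEN", 534),
    ("BENJAMIN", 730), ("SAMANTHA", 703), ("SAMUEL", 635), ("KATHERINE", 598),
    ("GREGORY", 576), ("CHRISTINE", 612), ("FRANK", 581), ("DEBRA", 508),
    ("ALEXANDER", 536), ("RACHEL", 650), ("RAYMOND", 576), ("CATHERINE", 526),
    ("PATRICK", 663), ("CAROLYN", 501), ("JACK", 446), ("JANET", 470),
    ("DENNIS", 534), ("RUTH", 468), ("JERRY", 533), ("MARIA", 647),
]
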