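# Hierarchical e-liquid flavor classification (category -> subcategory -> specific flavor).
# Columns: category, subcategory, keyword, aliases (';'-separated), ingredients (';'-separated
# category names; empty means the keyword belongs to its own category only).
category	subcategory	keyword	aliases	ingredients
fruit	berry	wildberry
fruit	berry	currant
fruit	berry	blackcurrant
fruit	berry	blackberry
fruit	berry	grape	grapes
fruit	berry	raspberry	raspberries
fruit	berry	blueberry	blueberries
fruit	berry	strawberry	strawberries
fruit	tropical	mango	mangoes
fruit	tropical	lychee
fruit	tropical	guava
fruit	tropical	passion fruit	passionfruit
fruit	tropical	pineapple
fruit	citrus	grapefruit
fruit	citrus	lime
fruit	citrus	orange
fruit	citrus	lemon
fruit	melon	cantaloupe
fruit	melon	honeydew
fruit	melon	melon
fruit	melon	watermelon
fruit	mixed_fruit	mango apricot
fruit	mixed_fruit	apple melon
fruit	mixed_fruit	nana berry
fruit	others	pomelo
fruit	others	papaya
fruit	others	apricot
fruit	others	dragon fruit	dragonfruit
fruit	others	pomegranate
fruit	others	cucumber
fruit	others	kiwi
fruit	others	pear
fruit	others	cherry	cherries
fruit	others	peach	peaches
fruit	others	coconut
fruit	others	banana	bananas
fruit	others	apple
sweets	dessert	mochi
sweets	dessert	pie
sweets	dessert	waffle
sweets	dessert	donut	doughnut
sweets	dessert	cake
sweets	dessert	s'more	smores
sweets	dessert	muffin
sweets	dessert	ice cream
sweets	dessert	cream
sweets	dessert	custard
sweets	dessert	macaron
sweets	dessert	granola
sweets	dessert	pastry
sweets	dessert	meringue
sweets	dessert	bread
sweets	dessert	cheesecake
sweets	dessert	cookie	cookies
sweets	candy	lollypop	lollipop
sweets	candy	jelly bean
sweets	candy	gummy bear	gummy bears
sweets	candy	cotton candy
sweets	candy	marshmallow
sweets	candy	bubble gum	bubblegum
sweets	candy	chocolate
sweets	others	cereal
sweets	others	honey
sweets	others	caramel
beverage	coffee	latte
beverage	coffee	mocha
beverage	coffee	cappuccino
beverage	coffee	espresso
beverage	coffee	coffee
beverage	tea	chai
beverage	tea	tea
beverage	juice	limeade
beverage	juice	lemonade
beverage	juice	apple juice
beverage	milk	yogurt
beverage	milk	milkshake
beverage	milk	milk
beverage	soft_drink	cola
beverage	soft_drink	coke
beverage	soft_drink	soda
beverage	others	energy drink
beverage	others	smoothie
tobacco	tobacco	classic tobacco
tobacco	tobacco	virginia tobacco
tobacco	tobacco	cigar
tobacco	tobacco	tobacco
menthol_or_mint	menthol	menthol
menthol_or_mint	mint	mint
menthol_or_mint	mint	peppermint
menthol_or_mint	mint	spearmint
mixed	mixed	strawberry mint		fruit;menthol_or_mint
mixed	mixed	peach cream		fruit;sweets
mixed	mixed	mango cola		fruit;beverage
mixed	mixed	honey tobacco		sweets;tobacco
others	alcohol	margarita
others	alcohol	whiskey
others	alcohol	rum
others	alcohol	bourbon
others	alcohol	cocktail
others	nuts	walnut
others	nuts	pecan
others	nuts	pistachio
others	nuts	hazelnut
others	nuts	almond
others	nuts	peanut butter
others	spice	vanilla
others	spice	cinnamon
others	others	pure vg
others	others	pure pg
others	others	pg/vg
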